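"""Sweep statistics against brute-force and closed-form oracles."""

import itertools

import numpy as np
import pytest

from ailmap import popgen, sim

from conftest import gm_from_chromatids


def brute_force_pi(chromatids, n_sites):
    """Mean pairwise difference per site over all chromatid pairs."""
    pairs = list(itertools.combinations(range(chromatids.shape[0]), 2))
    diffs = [np.sum(chromatids[i] != chromatids[j]) for i, j in pairs]
    return np.mean(diffs) / n_sites


class TestPi:
    def test_identical_sequences_have_zero_diversity(self):
        gm = gm_from_chromatids(np.ones((6, 20), dtype=np.int8),
                                positions=np.arange(20))
        out = popgen.pi_scan(gm, window_bp=10, step_bp=10, region=(0, 20))
        assert (out["value"].dropna() == 0).all()

    def test_two_chromatids_three_diffs_in_500_sites(self):
        c = np.zeros((2, 500), dtype=np.int8)
        c[1, [10, 200, 499]] = 1
        gm = gm_from_chromatids(c, positions=np.arange(500))
        out = popgen.pi_scan(gm, window_bp=500, step_bp=500, region=(0, 500))
        assert out["value"].iloc[0] == pytest.approx(3 / 500)

    def test_matches_all_pairs_oracle_on_six_chromatids(self, rng):
        c = (rng.random((6, 10)) < 0.4).astype(np.int8)
        gm = gm_from_chromatids(c, positions=np.arange(10))
        out = popgen.pi_scan(gm, window_bp=10, step_bp=10, region=(0, 10))
        assert out["value"].iloc[0] == pytest.approx(brute_force_pi(c, 10), abs=1e-12)

    def test_requires_two_chromatids(self):
        gm = gm_from_chromatids(np.zeros((2, 5), dtype=np.int8))
        gm.haplotypes = gm.haplotypes[:0]
        gm.samples = []
        with pytest.raises(ValueError):
            popgen.pi_scan(gm, 10, 10)

    def test_empty_window_flagged_undefined(self):
        gm = gm_from_chromatids(np.zeros((4, 2), dtype=np.int8), positions=[0, 90])
        out = popgen.pi_scan(gm, window_bp=10, step_bp=10, region=(0, 100))
        assert np.isnan(out["value"].iloc[3])


def textbook_tajimas_d(chromatids):
    """Independently coded Tajima (1989) D for a complete alignment."""
    n, m = chromatids.shape
    freq = chromatids.mean(axis=0)
    S = int(np.sum((freq > 0) & (freq < 1)))
    if S == 0:
        return np.nan
    pairs = list(itertools.combinations(range(n), 2))
    k_hat = np.mean([np.sum(chromatids[i] != chromatids[j]) for i, j in pairs])
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k_hat - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_monomorphic_bin_is_undefined_not_zero(self):
        gm = gm_from_chromatids(np.zeros((6, 10), dtype=np.int8),
                                positions=np.arange(10))
        out = popgen.tajimas_d(gm, bin_bp=10, region=(0, 10))
        assert np.isnan(out["value"].iloc[0])

    def test_zero_when_pi_equals_watterson(self):
        # n = 4: eight singleton sites (per-site pi 1/2) and three doubleton
        # sites (per-site pi 2/3) give pi_total = 6 = S / a1 with S = 11,
        # so the numerator vanishes exactly
        c = np.zeros((4, 11), dtype=np.int8)
        for j in range(8):
            c[j % 4, j] = 1          # singletons
        c[0:2, 8] = 1
        c[1:3, 9] = 1
        c[2:4, 10] = 1               # doubletons
        gm = gm_from_chromatids(c, positions=np.arange(11))
        out = popgen.tajimas_d(gm, bin_bp=11, region=(0, 11))
        assert out["value"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_formula_on_n4_s3_alignment(self):
        c = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]], dtype=np.int8)
        gm = gm_from_chromatids(c, positions=np.arange(3))
        out = popgen.tajimas_d(gm, bin_bp=3, region=(0, 3))
        assert out["value"].iloc[0] == pytest.approx(textbook_tajimas_d(c), abs=1e-12)

    def test_neutral_coalescent_windows_average_near_zero(self):
        msprime = pytest.importorskip("msprime")
        ts = msprime.sim_ancestry(samples=20, sequence_length=5_000_000,
                                  recombination_rate=1e-8, population_size=1e4,
                                  random_seed=11)
        ts = msprime.sim_mutations(ts, rate=1e-8, random_seed=12)
        geno = ts.genotype_matrix().T.astype(np.int8)   # (chromatids, sites)
        geno = np.clip(geno, 0, 1)
        pos = np.array([int(v.site.position) for v in ts.variants()])
        gm = gm_from_chromatids(geno, positions=pos)
        out = popgen.tajimas_d(gm, bin_bp=25_000, region=(0, 5_000_000))
        vals = out["value"].dropna()
        assert len(vals) >= 190
        assert abs(vals.mean()) < 0.3


class TestHapDiversity:
    def test_identical_chromatids_give_zero(self):
        gm = gm_from_chromatids(np.ones((6, 4), dtype=np.int8), positions=np.arange(4))
        out = popgen.hap_diversity(gm, bin_bp=4, region=(0, 4))
        assert out["value"].iloc[0] == 0.0

    def test_two_distinct_haplotypes_of_two(self):
        c = np.array([[0, 0], [1, 1]], dtype=np.int8)
        gm = gm_from_chromatids(c, positions=[0, 1])
        out = popgen.hap_diversity(gm, bin_bp=2, region=(0, 2))
        assert out["value"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_for_frequencies_half_quarter_quarter(self):
        c = np.array([[0, 0], [0, 0], [1, 0], [1, 1]], dtype=np.int8)
        gm = gm_from_chromatids(c, positions=[0, 1])
        out = popgen.hap_diversity(gm, bin_bp=2, region=(0, 2))
        assert out["value"].iloc[0] == pytest.approx((4 / 3) * (1 - 0.375))

    def test_unphased_input_rejected(self):
        gm = gm_from_chromatids(np.zeros((4, 3), dtype=np.int8), phased=False)
        with pytest.raises(ValueError, match="phased"):
            popgen.hap_diversity(gm)


def hudson_oracle(nA, cA, nB, cB):
    """Independently coded per-site Hudson Fst from allele counts."""
    p1, p2 = cA / nA, cB / nB
    num = (p1 - p2)**2 - p1 * (1 - p1) / (nA - 1) - p2 * (1 - p2) / (nB - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num / den


def _pop(count, n, m_extra=0):
    c = np.zeros((n, 1 + m_extra), dtype=np.int8)
    c[:count, 0] = 1
    return gm_from_chromatids(c, positions=np.arange(1 + m_extra))


class TestFst:
    def test_fixed_difference_gives_one(self):
        a = gm_from_chromatids(np.ones((6, 1), dtype=np.int8), positions=[0])
        b = gm_from_chromatids(np.zeros((6, 1), dtype=np.int8), positions=[0])
        out = popgen.fst(a, b)
        assert out["value"].iloc[0] == pytest.approx(1.0)

    def test_equal_frequencies_leave_only_the_finite_sample_term(self):
        # identical sample frequencies: the estimator reduces exactly to
        # the finite-sample correction -1/(n-1), vanishing as n grows
        a = _pop(3, 10)
        b = _pop(3, 10)
        out = popgen.fst(a, b)
        assert out["value"].iloc[0] == pytest.approx(hudson_oracle(10, 3, 10, 3), abs=1e-12)
        assert out["value"].iloc[0] == pytest.approx(-1 / 9, abs=1e-12)
        big_a, big_b = _pop(300, 1000), _pop(300, 1000)
        assert abs(popgen.fst(big_a, big_b)["value"].iloc[0]) < 1.5e-3

    def test_matches_hudson_oracle_at_12_of_20_vs_3_of_20(self):
        a = _pop(12, 20)
        b = _pop(3, 20)
        out = popgen.fst(a, b)
        assert out["value"].iloc[0] == pytest.approx(hudson_oracle(20, 12, 20, 3), abs=1e-12)

    def test_pooled_monomorphic_site_undefined(self):
        a = gm_from_chromatids(np.zeros((4, 1), dtype=np.int8), positions=[0])
        b = gm_from_chromatids(np.zeros((4, 1), dtype=np.int8), positions=[0])
        assert np.isnan(popgen.fst(a, b)["value"].iloc[0])

    def test_weir_cockerham_agrees_on_strong_differentiation(self):
        a = _pop(19, 20)
        b = _pop(1, 20)
        h = popgen.fst(a, b, estimator="hudson")["value"].iloc[0]
        w = popgen.fst(a, b, estimator="wc")["value"].iloc[0]
        assert h == pytest.approx(w, abs=0.05)


def enumeration_ehh(haps, core, idx):
    """Hand-enumerated homozygosity of extended haplotypes core..idx."""
    lo, hi = min(core, idx), max(core, idx)
    keys = [tuple(h[lo:hi + 1]) for h in haps]
    n = len(keys)
    counts = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    return sum(v * (v - 1) / 2 for v in counts.values()) / (n * (n - 1) / 2)


class TestEHHAndXPEHH:
    def test_single_haplotype_population_has_ehh_one_everywhere(self):
        haps = np.ones((5, 7), dtype=np.int8)
        _, ehh = popgen.ehh_curve(haps, 3)
        assert np.allclose(ehh, 1.0)

    def test_matches_enumeration_oracle_on_toy_panel(self, rng):
        haps = (rng.random((4, 9)) < 0.5).astype(np.int8)
        core = 4
        _, ehh = popgen.ehh_curve(haps, core)
        for j in range(9):
            assert ehh[j] == pytest.approx(enumeration_ehh(haps, core, j), abs=1e-12)

    def test_ehh_non_increasing_away_from_core(self, rng):
        haps = (rng.random((8, 15)) < 0.5).astype(np.int8)
        _, ehh = popgen.ehh_curve(haps, 7)
        assert np.all(np.diff(ehh[7:]) <= 1e-12)
        assert np.all(np.diff(ehh[7::-1]) <= 1e-12)

    def test_identical_populations_give_zero_raw_xpehh(self, rng):
        c = (rng.random((8, 11)) < 0.5).astype(np.int8)
        pos = np.arange(11) * 1000
        a = gm_from_chromatids(c, positions=pos)
        b = gm_from_chromatids(c.copy(), positions=pos)
        gmap = sim.GeneticMap(2.8, 0, 11_000)
        core = int(pos[5])
        raw = popgen.xpehh(a, b, core, gmap)
        assert raw == pytest.approx(0.0, abs=1e-12)

    def test_label_permutation_negates_raw_score(self, rng):
        pos = np.arange(11) * 1000
        gmap = sim.GeneticMap(2.8, 0, 11_000)
        a = gm_from_chromatids((rng.random((8, 11)) < 0.5).astype(np.int8), positions=pos)
        b = gm_from_chromatids((rng.random((8, 11)) < 0.6).astype(np.int8), positions=pos)
        core = int(pos[5])
        assert popgen.xpehh(a, b, core, gmap) == pytest.approx(
            -popgen.xpehh(b, a, core, gmap), abs=1e-12)

    def test_monomorphic_core_rejected(self, rng):
        pos = np.arange(5) * 1000
        c = np.zeros((4, 5), dtype=np.int8)
        gm = gm_from_chromatids(c, positions=pos)
        with pytest.raises(ValueError, match="monomorphic"):
            popgen.xpehh(gm, gm, 2000, sim.GeneticMap(2.8, 0, 5000))
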