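"""Simulator: founder draws, meiosis, AIL breeding, phenotypes."""

import numpy as np
import pytest
from scipy import stats

from ailmap import sim


def _uniform_pool(n_hap, m, rng, weights=None):
    haps = (rng.random((n_hap, m)) < 0.5).astype(np.int8)
    w = np.asarray(weights if weights is not None else np.full(n_hap, 1 / n_hap))
    return sim.FounderPoolSpec("P", haps, w)


class TestMakeFounders:
    def test_degenerate_single_haplotype_pool_gives_identical_chromatids(self, gmap):
        hap = np.array([[0, 1, 1, 0, 1]], dtype=np.int8)
        pool = sim.FounderPoolSpec("A", hap, np.array([1.0]))
        poolB = sim.FounderPoolSpec("B", 1 - hap, np.array([1.0]))
        founders = sim.make_founders(pool, poolB, 5, 1, seed=0, gmap=gmap)
        for f in founders[:5]:
            assert np.array_equal(f.haplotypes[0], hap[0])
            assert np.array_equal(f.haplotypes[1], hap[0])

    def test_realized_pool_frequencies_match_weights(self, gmap, rng):
        m = 20
        pool = _uniform_pool(2, m, rng, weights=[0.7, 0.3])
        pool.haplotype_pool[0] = 1
        pool.haplotype_pool[1] = 0
        poolB = _uniform_pool(1, m, rng)
        founders = sim.make_founders(pool, poolB, 500, 1, seed=42, gmap=gmap)
        draws = np.array([f.haplotypes[c, 0] for f in founders[:500] for c in range(2)])
        p_hat = draws.mean()
        se = np.sqrt(0.7 * 0.3 / 1000)
        assert abs(p_hat - 0.7) < 3 * se

    def test_fixed_opposite_pools_give_delta_af_one(self, gmap):
        hapA = np.ones((1, 4), dtype=np.int8)
        hapB = np.zeros((1, 4), dtype=np.int8)
        poolA = sim.FounderPoolSpec("A", hapA, np.array([1.0]))
        poolB = sim.FounderPoolSpec("B", hapB, np.array([1.0]))
        founders = sim.make_founders(poolA, poolB, 5, 5, seed=0, gmap=gmap)
        afA = np.mean([f.haplotypes for f in founders[:5]])
        afB = np.mean([f.haplotypes for f in founders[5:]])
        assert abs(afA - afB) == 1.0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sim.FounderPoolSpec("A", np.empty((0, 5), dtype=np.int8), np.array([]))

    def test_mismatched_haplotype_lengths_rejected(self, gmap, rng):
        poolA = _uniform_pool(2, 5, rng)
        poolB = _uniform_pool(2, 7, rng)
        with pytest.raises(ValueError, match="mismatched"):
            sim.make_founders(poolA, poolB, 2, 2, seed=0, gmap=gmap)


class TestMeiosis:
    def test_zero_rate_copies_one_parental_chromatid(self, rng):
        gmap = sim.GeneticMap(0.0, 0, 10_000)
        positions = np.arange(0, 10_000, 1000)
        pool = _uniform_pool(2, 10, rng)
        parent = sim.make_founders(pool, pool, 1, 1, seed=1, gmap=gmap)[0]
        hap, painting = sim.meiosis(parent, gmap, positions, rng)
        assert any(np.array_equal(hap, parent.haplotypes[c]) for c in range(2))
        assert painting in parent.paintings

    def test_mean_crossovers_match_map_length(self, rng):
        # 3.1 Mb at 2.8 cM/Mb -> 0.0868 expected crossovers per meiosis
        gmap = sim.GeneticMap()
        positions = sim.snp_grid(gmap, 100_000)
        pool = _uniform_pool(2, positions.size, rng)
        parent = sim.make_founders(pool, pool, 1, 1, seed=2, gmap=gmap)[0]
        # count via Poisson draws made by meiosis: infer from painting switches
        # of a parent with distinguishable chromatids
        parent.paintings = [[(gmap.region_start_bp, gmap.region_end_bp, "c0")],
                            [(gmap.region_start_bp, gmap.region_end_bp, "c1")]]
        n = 100_000
        counts = np.empty(n)
        for i in range(n):
            _, painting = sim.meiosis(parent, gmap, positions, rng)
            counts[i] = len(painting) - 1
        expected = 3.1 * 2.8 / 100
        se = np.sqrt(expected / n)   # Poisson mean SE
        # painting-switch count undercounts crossovers between identical
        # chromatids only when two breaks cancel; with 2 labels a double
        # break within one interval cancels, a rare O(lambda^2) event
        assert abs(counts.mean() - expected) < 3 * se + expected**2

    def test_large_map_mean_crossovers_and_poisson_fit(self, rng):
        gmap = sim.GeneticMap(100.0 / 1.0, 0, 1_000_000)  # 100 cM region
        positions = np.arange(0, 1_000_000, 5000)
        pool = _uniform_pool(2, positions.size, rng)
        parent = sim.make_founders(pool, pool, 1, 1, seed=3, gmap=gmap)[0]
        parent.paintings = [[(0, 1_000_000, "c0")], [(0, 1_000_000, "c1")]]
        draws = np.array([rng.poisson(gmap.length_morgans) for _ in range(10_000)])
        assert abs(draws.mean() - 1.0) < 3 * np.sqrt(1.0 / 10_000)
        # chi-square goodness of fit of the crossover-count distribution
        obs = np.bincount(draws, minlength=6)[:6].astype(float)
        k = np.arange(6)
        exp = stats.poisson.pmf(k, 1.0) * draws.size
        exp[-1] += (1 - stats.poisson.cdf(5, 1.0)) * draws.size
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, df=5) > 0.001

    def test_zero_length_region_rejected(self, rng):
        with pytest.raises(ValueError):
            sim.GeneticMap(1.0, 100, 100)


class TestSimulateAil:
    def test_zero_rate_f1_chromatids_are_founder_copies(self, gmap, rng):
        flat = sim.GeneticMap(0.0, gmap.region_start_bp, gmap.region_end_bp)
        positions = sim.snp_grid(flat, 50_000)
        poolA = _uniform_pool(3, positions.size, rng)
        poolB = _uniform_pool(3, positions.size, rng)
        poolA.label, poolB.label = "A", "B"
        founders = sim.make_founders(poolA, poolB, 4, 4, seed=5, gmap=flat)
        ped = sim.simulate_ail(founders, [20], flat, positions, seed=6)
        founder_chromatids = {h.tobytes() for f in founders for h in f.haplotypes}
        for child in ped[1]:
            for c in range(2):
                assert child.haplotypes[c].tobytes() in founder_chromatids
                assert len(child.paintings[c]) == 1

    def test_f1_is_interline_heterozygous(self, gmap, rng):
        positions = sim.snp_grid(gmap, 50_000)
        poolA = sim.FounderPoolSpec("A", np.ones((1, positions.size), np.int8), [1.0])
        poolB = sim.FounderPoolSpec("B", np.zeros((1, positions.size), np.int8), [1.0])
        founders = sim.make_founders(poolA, poolB, 4, 4, seed=5, gmap=gmap)
        ped = sim.simulate_ail(founders, [10], gmap, positions, seed=6)
        for child in ped[1]:
            assert sorted(child.paintings[0][0][2] + child.paintings[1][0][2]) == ["A", "B"]

    def test_recombinant_fraction_grows_with_generation(self, gmap, grid, rng):
        poolA, poolB = sim.make_divergent_pools(grid, rng)
        founders = sim.make_founders(poolA, poolB, 8, 8, seed=1, gmap=gmap)
        fracs = []
        for reps in range(3):
            ped = sim.simulate_ail(founders, [60] * 8, gmap, grid, seed=100 + reps)
            per_gen = []
            for g in (2, 5, 8):
                n_rec = sum(len(ind.paintings[c]) > 1
                            for ind in ped[g] for c in range(2))
                per_gen.append(n_rec / (2 * len(ped[g])))
            fracs.append(per_gen)
        mean = np.mean(fracs, axis=0)
        assert mean[0] < mean[1] < mean[2]

    def test_same_seed_reproduces_pedigree_exactly(self, gmap, grid):
        poolA, poolB = sim.make_divergent_pools(grid, seed=3)
        founders = sim.make_founders(poolA, poolB, 6, 6, seed=4, gmap=gmap)
        p1 = sim.simulate_ail(founders, [20, 30], gmap, grid, seed=9)
        p2 = sim.simulate_ail(founders, [20, 30], gmap, grid, seed=9)
        for g in p1:
            for a, b in zip(p1[g], p2[g]):
                assert a.id == b.id and a.sire_id == b.sire_id
                assert np.array_equal(a.haplotypes, b.haplotypes)
                assert a.paintings == b.paintings

    def test_single_sex_generation_rejected(self, gmap, grid, rng):
        poolA, poolB = sim.make_divergent_pools(grid, rng)
        founders = sim.make_founders(poolA, poolB, 4, 4, seed=1, gmap=gmap)
        for f in founders:
            f.sex = "M"
        with pytest.raises(ValueError, match="sex"):
            sim.simulate_ail(founders, [10], gmap, grid, seed=2)


class TestPaintingConsistency:
    def test_paintings_tile_region_and_match_line_alleles(self, gmap, grid):
        # fully diagnostic pools: allele equals origin everywhere, so the
        # painting determines the haplotype exactly
        poolA = sim.FounderPoolSpec("A", np.ones((2, grid.size), np.int8), [0.5, 0.5])
        poolB = sim.FounderPoolSpec("B", np.zeros((2, grid.size), np.int8), [0.5, 0.5])
        founders = sim.make_founders(poolA, poolB, 6, 6, seed=11, gmap=gmap)
        ped = sim.simulate_ail(founders, [30, 30, 30], gmap, grid, seed=12)
        for g, inds in ped.items():
            for ind in inds:
                for c in range(2):
                    sim.check_painting(ind.paintings[c], gmap.region_start_bp,
                                       gmap.region_end_bp)
                    for s, e, lab in ind.paintings[c]:
                        lo, hi = np.searchsorted(grid, [s, e])
                        expect = 1 if lab == "A" else 0
                        assert np.all(ind.haplotypes[c, lo:hi] == expect)

    def test_founder_label_frequency_stays_near_half(self, gmap, grid):
        poolA = sim.FounderPoolSpec("A", np.ones((1, grid.size), np.int8), [1.0])
        poolB = sim.FounderPoolSpec("B", np.zeros((1, grid.size), np.int8), [1.0])
        founders = sim.make_founders(poolA, poolB, 10, 10, seed=21, gmap=gmap)
        length = gmap.length_bp
        fracs = []
        for rep in range(6):
            ped = sim.simulate_ail(founders, [50] * 5, gmap, grid, seed=300 + rep)
            tot = a_len = 0
            for ind in ped[5]:
                for painting in ind.paintings:
                    for s, e, lab in painting:
                        tot += e - s
                        if lab == "A":
                            a_len += e - s
            fracs.append(a_len / tot)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.5) < max(3 * se, 0.1)


class TestPhenotypes:
    def test_no_effects_no_noise_gives_exact_covariate_sum(self, gmap, grid, rng):
        poolA, poolB = sim.make_divergent_pools(grid, rng)
        founders = sim.make_founders(poolA, poolB, 4, 4, seed=1, gmap=gmap)
        arch = sim.QTLArchitecture(loci=[], residual_sd_g=0.0)
        table = sim.simulate_phenotypes(founders, arch, grid, seed=2)
        for _, row in table.iterrows():
            expect = arch.baseline_g + (arch.sex_effect_g if row.sex == "M" else 0.0)
            expect += arch.batch_effects_g[row.batch % 4]
            assert row.phenotype_g == pytest.approx(expect)

    def test_single_locus_genetic_variance_matches_2pqa2(self, gmap, grid, rng):
        # Hardy-Weinberg draws at one site
        n = 2000
        p, a = 0.3, 50.0
        inds = []
        for i in range(n):
            haps = (rng.random((2, grid.size)) < p).astype(np.int8)
            inds.append(sim.PedigreeIndividual(
                id=f"x{i}", generation=0, sire_id=None, dam_id=None,
                sex="F", batch=0, haplotypes=haps,
                paintings=[[(gmap.region_start_bp, gmap.region_end_bp, "A")]] * 2))
        arch = sim.QTLArchitecture(loci=[sim.QTLLocus(int(grid[10]), a, 1)],
                                   sex_effect_g=0.0, batch_effects_g=(0.0,),
                                   residual_sd_g=0.0)
        table = sim.simulate_phenotypes(inds, arch, grid, seed=3)
        var = table["phenotype_g"].var(ddof=1)
        expect = 2 * p * (1 - p) * a**2
        # sampling error of a variance estimate at n=2000
        assert abs(var - expect) < 4 * expect * np.sqrt(2 / n)

    def test_two_coupled_loci_add_twice_the_dosage_covariance(self, gmap, grid, rng):
        n = 500
        inds = []
        j1, j2 = 10, 11
        for i in range(n):
            carrier = rng.random(2) < 0.4     # full coupling: same allele at both
            haps = np.zeros((2, grid.size), np.int8)
            haps[:, j1] = carrier
            haps[:, j2] = carrier
            inds.append(sim.PedigreeIndividual(
                id=f"x{i}", generation=0, sire_id=None, dam_id=None,
                sex="F", batch=0, haplotypes=haps,
                paintings=[[(gmap.region_start_bp, gmap.region_end_bp, "A")]] * 2))
        a1, a2 = 30.0, 20.0
        arch = sim.QTLArchitecture(
            loci=[sim.QTLLocus(int(grid[j1]), a1, 1), sim.QTLLocus(int(grid[j2]), a2, 1)],
            sex_effect_g=0.0, batch_effects_g=(0.0,), residual_sd_g=0.0)
        table = sim.simulate_phenotypes(inds, arch, grid, seed=4)
        d1 = np.array([(ind.haplotypes[:, j1] == 1).sum() for ind in inds], float)
        d2 = np.array([(ind.haplotypes[:, j2] == 1).sum() for ind in inds], float)
        expect = (a1**2 * d1.var(ddof=1) + a2**2 * d2.var(ddof=1)
                  + 2 * a1 * a2 * np.cov(d1, d2)[0, 1])
        assert table["phenotype_g"].var(ddof=1) == pytest.approx(expect, rel=1e-9)

    def test_off_grid_locus_rejected(self, gmap, grid, rng):
        poolA, poolB = sim.make_divergent_pools(grid, rng)
        founders = sim.make_founders(poolA, poolB, 2, 2, seed=1, gmap=gmap)
        arch = sim.QTLArchitecture(loci=[sim.QTLLocus(123, 10.0, 1)])
        with pytest.raises(ValueError, match="grid"):
            sim.simulate_phenotypes(founders, arch, grid, seed=0)


class TestRelationshipMatrix:
    def test_tabular_values_on_a_nuclear_family(self, gmap, grid, rng):
        poolA, poolB = sim.make_divergent_pools(grid, rng)
        founders = sim.make_founders(poolA, poolB, 2, 2, seed=1, gmap=gmap)
        ped = sim.simulate_ail(founders, [4], gmap, grid, seed=2)
        kids = ped[1]
        A = sim.pedigree_relationship_matrix(ped, kids)
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                shared = (kids[i].sire_id == kids[j].sire_id) + \
                         (kids[i].dam_id == kids[j].dam_id)
                assert A[i, j] == pytest.approx({0: 0.0, 1: 0.25, 2: 0.5}[shared])
            assert A[i, i] == pytest.approx(1.0)
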