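"""Operating-characteristic experiments on simulated intercross data.

These routines measure the package's headline properties — haplotype
substitution-effect recovery, segment variance-explained recovery,
Q-region recovery by the full pipeline, backward-elimination power and
null behavior, and association-scan type-I error — under the simulator's
default study conditions (an F9 advanced intercross of n = 600 over a
3.1 Mb region with 1,550 grid SNPs, residual SD 100 g).  They are used by
the test suite and by the reproduction script; all randomness flows from
the single seed argument.
"""

from __future__ import annotations

import numpy as np

from . import assoc, haplo, sim
from .config import load_config
from .genotypes import GenotypeMatrix
from .pipeline import run_all

_FINE_REGION = (168_600_000, 169_800_000)   # 1.2 Mb fine-mapping interval


def _simulate_f9(rng: np.random.Generator, n_final: int = 600,
                 qtl_positions: tuple[int, ...] = (169_240_000, 169_650_000),
                 qtl_effects: tuple[float, ...] = (120.0, 90.0),
                 n_intermediate: int = 150,
                 residual_sd: float = 100.0):
    """One F9 AIL replicate under the default study conditions."""
    gmap = sim.GeneticMap()
    positions = sim.snp_grid(gmap)
    poolA, poolB = sim.make_divergent_pools(positions, rng,
                                            qtl_positions=list(qtl_positions))
    founders = sim.make_founders(poolA, poolB, 16, 15, rng, gmap)
    sizes = [n_intermediate] * 8 + [n_final]
    pedigree = sim.simulate_ail(founders, sizes, gmap, positions, rng)
    final = pedigree[9]
    arch = sim.QTLArchitecture(
        loci=[sim.QTLLocus(p, e, 1) for p, e in zip(qtl_positions, qtl_effects)],
        residual_sd_g=residual_sd)
    pheno = sim.simulate_phenotypes(final, arch, positions, rng)
    return gmap, positions, pedigree, final, pheno, arch


def _sex_covariate(final) -> np.ndarray:
    return np.array([[1.0 if ind.sex == "M" else 0.0] for ind in final])


# ----------------------------------------------------------------------
# haplotype substitution-effect recovery
# ----------------------------------------------------------------------

def effect_recovery_experiment(seed: int, n_reps: int = 50,
                               n_final: int = 600) -> dict:
    """Planted haplotype substitution effects spanning -59 to +65 g on
    simulated F9 data (n = 600, residual SD 100 g).

    Per replicate, eight tag SNPs across the 1.2 Mb fine-mapping interval
    define the haplotype classes (rare ones pooled into "Other"); true
    effects are spread linearly over [-59, +65] g, centered to satisfy the
    sum-to-zero identifiability constraint, and the phenotype includes a
    sex effect plus N(0, 100 g) noise.  Reports the fraction of estimated
    effects falling within 2 SE of their planted values, aggregated over
    replicates.
    """
    root = np.random.SeedSequence(seed)
    hits = total = 0
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        gmap, positions, _, final, _, _ = _simulate_f9(rng, n_final=n_final)
        tag_pos = np.linspace(_FINE_REGION[0] + 50_000, _FINE_REGION[1] - 50_000, 8)
        tag_idx = np.searchsorted(positions, tag_pos)
        pairs = [(tuple(int(a) for a in ind.haplotypes[0, tag_idx]),
                  tuple(int(a) for a in ind.haplotypes[1, tag_idx]))
                 for ind in final]
        _, freqs, Z = haplo.phased_dosage_matrix(pairs)
        _, freqs_p, Zp = haplo.group_rare(freqs, Z, 0.01)
        k = Zp.shape[1]
        u_true = np.linspace(-59.0, 65.0, k)
        u_true = u_true - u_true.mean()          # sum-to-zero truth
        X_sex = _sex_covariate(final)
        y = (950.0 + Zp @ u_true + 250.0 * X_sex[:, 0]
             + rng.normal(0.0, 100.0, len(final)))
        model = haplo.substitution_effects(y, Zp, X_sex)
        within = np.abs(model.effects - u_true) <= 2.0 * model.effect_se
        hits += int(within.sum())
        total += k
    return {"coverage_2se": hits / total, "n_effects": total, "n_reps": n_reps}


# ----------------------------------------------------------------------
# segment variance-explained recovery
# ----------------------------------------------------------------------

def variance_explained_experiment(seed: int, n_reps: int = 50,
                                  n_final: int = 600,
                                  target_fraction: float = 0.15) -> dict:
    """Recovery of a segment planted to contribute 15% of Vg.

    The focal-region QTL is a single divergently fixed locus scaled to
    contribute ``target_fraction`` of the additive genetic variance; the
    remaining genetic variance comes from 60 unlinked background loci
    transmitted through the same pedigree (the stand-in for the rest of
    the genome).  Vg is re-estimated per replicate by REML against the
    pedigree additive relationship matrix — the single-region analogue of
    a genome-wide GRM, since additive covariance is Vg * A for any
    architecture transmitted through the pedigree.  The segment is
    represented by its genotype classes and the mean recovered fraction
    over replicates is reported.
    """
    root = np.random.SeedSequence(seed)
    segment_pos = 169_240_000
    n_bg = 60
    vg_target = 8000.0                     # grams^2
    seg_var = target_fraction * vg_target
    a_seg = np.sqrt(seg_var / 0.5)         # 2 p q a^2 with p = 0.5
    bg_var = vg_target - seg_var
    b_eff = np.sqrt(bg_var / (n_bg * 0.5))
    fractions = []
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        gmap, positions, pedigree, final, _, _ = _simulate_f9(
            rng, n_final=n_final, qtl_positions=(segment_pos,),
            qtl_effects=(a_seg,))
        sim.simulate_background_loci(pedigree, n_bg, rng)
        bg_effects = np.full(n_bg, b_eff)
        arch = sim.QTLArchitecture(loci=[sim.QTLLocus(segment_pos, a_seg, 1)],
                                   residual_sd_g=100.0)
        sim.simulate_phenotypes(final, arch, positions, rng,
                                background_effects=bg_effects)
        y = np.array([ind.phenotype for ind in final])
        cov = _sex_covariate(final)
        seg_idx = int(np.searchsorted(positions, segment_pos))
        region_dos = np.stack([ind.haplotypes.sum(axis=0) for ind in final]).astype(float)
        K = sim.pedigree_relationship_matrix(pedigree, final)
        vc = assoc.fit_null(y, cov, K)
        classes = region_dos[:, seg_idx].astype(int)
        frac = assoc.variance_explained(classes, y, cov, vc)
        fractions.append(frac)
    fractions = np.array(fractions)
    return {"mean_fraction": float(fractions.mean()),
            "sd_fraction": float(fractions.std(ddof=1)),
            "target": target_fraction, "n_reps": n_reps}


# ----------------------------------------------------------------------
# pipeline Q-region recovery
# ----------------------------------------------------------------------

DEMO_Q_INTERVALS = [(168_700_000, 168_760_000),
                    (169_100_000, 169_200_000),
                    (169_500_000, 169_560_000)]


def demo_config(seed: int, out_dir: str) -> dict:
    """Demo pipeline configuration with three planted shared Q intervals."""
    return load_config(overrides={
        "seed": int(seed),
        "out_dir": out_dir,
        "sim": {
            "generation_sizes": [100] * 8 + [300],
            "q_intervals": [list(iv) for iv in DEMO_Q_INTERVALS],
        },
        "popgen": {"xpehh_core_step": 25},
    })


def qregion_recovery_experiment(seed: int, out_dir: str) -> dict:
    """Fraction of planted Q-interval length overlapped by recovered
    Q regions after an end-to-end pipeline run."""
    cfg = demo_config(seed, out_dir)
    results = run_all(cfg)
    regions = results["share-scan"]["regions"]
    covered = sum(max(0, min(b, r.end) - max(a, r.start))
                  for a, b in DEMO_Q_INTERVALS for r in regions)
    planted = sum(b - a for a, b in DEMO_Q_INTERVALS)
    return {"overlap_fraction": covered / planted,
            "n_regions": len(regions),
            "besnps": results["haplo-fit"]["elimination"].retained}


# ----------------------------------------------------------------------
# backward elimination: power and null behavior
# ----------------------------------------------------------------------

def _candidate_grid(positions: np.ndarray, causal_pos: tuple[int, ...],
                    n_null: int, rng: np.random.Generator,
                    dosages: np.ndarray,
                    r2_max: float = 0.1,
                    min_maf: float = 0.05) -> np.ndarray:
    """Causal sites plus approximately independent common null tags.

    Null candidates are common SNPs (MAF >= min_maf) screened so that no
    candidate pair — null-null or null-causal — exceeds r^2 of ``r2_max``
    (the structure-analysis pruning threshold, giving approximate linkage
    equilibrium).  In a deep-intercross region, unscreened tags sit in
    near-perfect LD with a causal site and exact retention is not
    identifiable; the region supports only a handful of such independent
    tags, so experiments top the panel up with unlinked background
    markers.
    """
    causal_idx = list(np.searchsorted(positions, causal_pos))
    p = np.nanmean(dosages, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    centered = dosages - np.nanmean(dosages, axis=0)
    sd = centered.std(axis=0)
    pool = [j for j in np.nonzero(maf >= min_maf)[0] if j not in causal_idx and sd[j] > 0]
    rng.shuffle(pool)
    chosen: list[int] = []
    for j in pool:
        if len(chosen) >= n_null:
            break
        ok = True
        for k in causal_idx + chosen:
            if sd[k] == 0:
                continue
            r = float(np.mean(centered[:, j] * centered[:, k]) / (sd[j] * sd[k]))
            if r * r > r2_max:
                ok = False
                break
        if ok:
            chosen.append(j)
    return np.sort(np.array(causal_idx + chosen, dtype=int))


def _hybrid_panel(rng, pedigree, final, positions, causal, n_null: int = 28):
    """Candidate panel mirroring the modeled design: the causal loci, the
    region's approximately independent tags, and unlinked background
    markers (the stand-in for the study's outside-QTL control markers)
    topping the null set up to ``n_null``."""
    dos = np.stack([ind.haplotypes.sum(axis=0) for ind in final]).astype(float)
    idx = _candidate_grid(positions, causal, n_null, rng, dos)
    G = dos[:, idx]
    ids = [f"s{positions[j]}" for j in idx]
    pos = list(positions[idx])
    n_missing = n_null + len(causal) - idx.size
    if n_missing > 0:
        sim.simulate_background_loci(pedigree, n_missing, rng, founder_freq=0.4)
        bg = np.stack([ind.background.sum(axis=1) for ind in final]).astype(float)
        keep = [j for j in range(n_missing) if np.ptp(bg[:, j]) > 0]
        G = np.column_stack([G, bg[:, keep]])
        ids += [f"bg{j}" for j in keep]
        pos += [-1_000_000 * (j + 1) for j in keep]
    return G, ids, np.array(pos)


def besnp_recovery_experiment(seed: int, n_reps: int = 25,
                              n_final: int = 600) -> dict:
    """Backward elimination on F9 replicates with two planted causal SNPs
    among 28 approximately independent null candidates; success = both
    causal SNPs retained."""
    root = np.random.SeedSequence(seed)
    causal = (169_240_000, 169_650_000)
    successes = 0
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        gmap, positions, pedigree, final, pheno, _ = _simulate_f9(rng, n_final=n_final)
        G, ids, pos = _hybrid_panel(rng, pedigree, final, positions, causal)
        y = pheno["phenotype_g"].values
        cov = np.column_stack([_sex_covariate(final)[:, 0],
                               pheno["batch"].values.astype(float)])
        res = haplo.backward_elimination(y, G, ids, pos,
                                         covariates=cov, fdr=0.05)
        if all(f"s{p}" in res.retained for p in causal):
            successes += 1
    return {"recovery_rate": successes / n_reps, "n_reps": n_reps}


def null_besnp_experiment(seed: int, n_reps: int = 50,
                          n_final: int = 400) -> dict:
    """Backward elimination on permuted phenotypes: fraction of replicates
    returning an empty retained set.

    As in the scan calibration, the phenotype is permuted within sex
    strata and sex stays in the model, matching how the elimination is
    run on real data.
    """
    root = np.random.SeedSequence(seed)
    empties = 0
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        gmap, positions, pedigree, final, pheno, _ = _simulate_f9(
            rng, n_final=n_final, n_intermediate=100)
        G, ids, pos = _hybrid_panel(rng, pedigree, final, positions,
                                    (169_240_000, 169_650_000))
        y = pheno["phenotype_g"].values.copy()
        sex = np.array([ind.sex for ind in final])
        for s in np.unique(sex):
            stratum = np.nonzero(sex == s)[0]
            y[stratum] = y[rng.permutation(stratum)]
        res = haplo.backward_elimination(y, G, ids, pos,
                                        covariates=_sex_covariate(final), fdr=0.05)
        if not res.retained:
            empties += 1
    return {"empty_rate": empties / n_reps, "n_reps": n_reps}


# ----------------------------------------------------------------------
# association-scan null calibration
# ----------------------------------------------------------------------

def type1_error_experiment(seed: int, n_final: int = 400,
                           n_null_snps: int = 500) -> dict:
    """Empirical type-I error of the mixed-model scan at alpha = 0.05 on a
    permuted phenotype against null SNPs.

    The phenotype is permuted within sex strata so the covariate
    structure is preserved while the genotype-phenotype link is broken.
    The null SNPs are unlinked background loci transmitted through the
    same pedigree: their genotype vectors are mutually independent given
    the pedigree, so the binomial reference for the rejection count is
    valid (focal-region sites stay mutually correlated even after LD
    pruning, which invalidates it).  The mixed model uses the pedigree
    additive relationship matrix as its GRM (a marker GRM restricted to
    one 3 Mb region has a near-degenerate spectrum that destabilizes
    REML; see the methods note).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gmap, positions, pedigree, final, pheno, _ = _simulate_f9(
        rng, n_final=n_final, n_intermediate=100)
    sim.simulate_background_loci(pedigree, n_null_snps, rng, founder_freq=0.4)
    haps = np.stack([ind.background for ind in final]).astype(np.int8)  # (n, loci, 2)
    gm_null = GenotypeMatrix("bg", np.arange(n_null_snps) * 1000,
                             np.array([f"bg{j}" for j in range(n_null_snps)]),
                             [ind.id for ind in final], haps, phased=True)
    y = pheno["phenotype_g"].values.copy()
    sex = np.array([ind.sex for ind in final])
    for s in np.unique(sex):
        stratum = np.nonzero(sex == s)[0]
        y[stratum] = y[rng.permutation(stratum)]
    cov = _sex_covariate(final)
    K = sim.pedigree_relationship_matrix(pedigree, final)
    vc = assoc.fit_null(y, cov, K)
    table = assoc.assoc_scan(gm_null, y, cov, vc, K)
    pvals = table["p"].dropna().values
    alpha = 0.05
    rate = float((pvals < alpha).mean())
    se = float(np.sqrt(alpha * (1 - alpha) / pvals.size))
    return {"type1_error": rate, "n_tests": int(pvals.size),
            "binomial_se": se, "alpha": alpha}
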