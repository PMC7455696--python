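"""Tag-SNP haplotype analysis: EM frequency estimation, rare-haplotype
grouping, substitution effects under Y = X beta + Z u + e, and
backward-elimination multi-locus SNP selection at an FDR threshold.

The haplotype model treats each individual's pair of tag-SNP haplotypes
as alleles of a single multi-allelic locus: Y is the trait vector, X the
covariate design (sex in the modeled study), Z the per-individual
haplotype dosage design (0/1/2 per haplotype column including a pooled
"Other" column, each row summing to 2), beta the covariate effects and u
the per-haplotype substitution effects in grams, estimated under a
sum-to-zero contrast since no reference haplotype is privileged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

Haplotype = tuple[int, ...]


# ----------------------------------------------------------------------
# EM haplotype frequency estimation
# ----------------------------------------------------------------------

@dataclass
class EMResult:
    haplotypes: list[Haplotype]
    frequencies: np.ndarray
    posteriors: list[list[tuple[int, int, float]]]   # per individual: (h1, h2, prob)
    loglik: float
    n_iter: int

    def frequency_table(self) -> pd.DataFrame:
        strings = ["".join(map(str, h)) for h in self.haplotypes]
        return pd.DataFrame({"haplotype": strings, "frequency": self.frequencies})


def _compatible_pairs(genotype: np.ndarray) -> list[tuple[Haplotype, Haplotype]]:
    """All unordered phase-compatible haplotype pairs for one genotype
    vector of 0/1/2 dosages."""
    het = np.nonzero(genotype == 1)[0]
    base = np.where(genotype == 2, 1, 0)
    if het.size == 0:
        h = tuple(int(v) for v in base)
        return [(h, h)]
    pairs = []
    # fix the first het site on haplotype 1 to halve the enumeration
    for bits in product((0, 1), repeat=het.size - 1):
        h1 = base.copy()
        h2 = base.copy()
        h1[het[0]] = 1
        h2[het[0]] = 0
        for site, bit in zip(het[1:], bits):
            h1[site] = bit
            h2[site] = 1 - bit
        pairs.append((tuple(int(v) for v in h1), tuple(int(v) for v in h2)))
    return pairs


def em_haplotype_freqs(
    genotypes: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
    max_het: int = 16,
) -> EMResult:
    """EM haplotype frequencies from unphased tag-SNP genotypes.

    ``genotypes`` is (n_individuals, n_tag_snps) of 0/1/2 dosages with no
    missing values.  Initialization is uniform over the haplotypes
    compatible with the sample, so the result is deterministic.  The
    log-likelihood is non-decreasing every iteration (asserted) and
    iteration stops when the largest frequency change drops below ``tol``.
    """
    g = np.asarray(genotypes)
    if g.ndim != 2:
        raise ValueError("genotypes must be 2-D (individuals x tag SNPs)")
    if np.any((g < 0) | (g > 2)):
        raise ValueError("genotype dosages must be 0/1/2 with no missing values")
    n = g.shape[0]
    pair_lists = []
    hap_index: dict[Haplotype, int] = {}
    for i in range(n):
        if int((g[i] == 1).sum()) > max_het:
            raise ValueError(
                f"individual {i} has more than {max_het} heterozygous tag SNPs; "
                "the diplotype space is not enumerable")
        pairs = _compatible_pairs(g[i])
        idx_pairs = []
        for h1, h2 in pairs:
            for h in (h1, h2):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
            idx_pairs.append((hap_index[h1], hap_index[h2]))
        pair_lists.append(idx_pairs)
    haplotypes = [h for h, _ in sorted(hap_index.items(), key=lambda kv: kv[1])]
    k = len(haplotypes)
    freqs = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        counts = np.zeros(k)
        ll = 0.0
        posteriors = []
        for idx_pairs in pair_lists:
            w = np.array([(2.0 if a != b else 1.0) * freqs[a] * freqs[b]
                          for a, b in idx_pairs])
            tot = w.sum()
            if tot <= 0:
                raise ValueError("individual incompatible with every haplotype pair")
            w /= tot
            ll += np.log(tot)
            posteriors.append([(a, b, float(p)) for (a, b), p in zip(idx_pairs, w)])
            for (a, b), p in zip(idx_pairs, w):
                counts[a] += p
                counts[b] += p
        assert ll >= prev_ll - 1e-9, "EM log-likelihood decreased"
        prev_ll = ll
        new_freqs = counts / (2.0 * n)
        delta = float(np.max(np.abs(new_freqs - freqs)))
        freqs = new_freqs
        if delta < tol:
            break
    return EMResult(haplotypes, freqs, posteriors, prev_ll, it)


def haplotype_dosage_matrix(em: EMResult) -> np.ndarray:
    """Expected per-individual haplotype dosages (n x k), each row
    summing to 2, from the EM posteriors."""
    n = len(em.posteriors)
    Z = np.zeros((n, len(em.haplotypes)))
    for i, pairs in enumerate(em.posteriors):
        for a, b, p in pairs:
            Z[i, a] += p
            Z[i, b] += p
    return Z


def phased_dosage_matrix(haplotype_pairs: list[tuple[Haplotype, Haplotype]]):
    """Dosage matrix directly from known (phased) haplotype pairs;
    returns (haplotypes, frequencies, Z)."""
    hap_index: dict[Haplotype, int] = {}
    for h1, h2 in haplotype_pairs:
        for h in (h1, h2):
            hap_index.setdefault(h, len(hap_index))
    haplotypes = [h for h, _ in sorted(hap_index.items(), key=lambda kv: kv[1])]
    Z = np.zeros((len(haplotype_pairs), len(haplotypes)))
    for i, (h1, h2) in enumerate(haplotype_pairs):
        Z[i, hap_index[h1]] += 1
        Z[i, hap_index[h2]] += 1
    freqs = Z.sum(axis=0) / (2.0 * len(haplotype_pairs))
    return haplotypes, freqs, Z


# ----------------------------------------------------------------------
# rare-haplotype grouping
# ----------------------------------------------------------------------

def group_rare(
    frequencies: np.ndarray,
    Z: np.ndarray,
    min_freq: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool haplotypes at frequency <= ``min_freq`` into one "Other" class.

    Haplotypes with frequency strictly above the threshold are retained
    individually; the rest are merged into a single class whose frequency
    is their sum and whose Z column is the sum of their columns.  Returns
    (major indices into the input, pooled frequencies, pooled Z); the
    "Other" column, when present, is last.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    major = np.nonzero(frequencies > min_freq)[0]
    rare = np.nonzero(frequencies <= min_freq)[0]
    if rare.size == 0:
        return major, frequencies[major], Z[:, major]
    freqs = np.concatenate([frequencies[major], [frequencies[rare].sum()]])
    Zp = np.column_stack([Z[:, major], Z[:, rare].sum(axis=1)])
    return major, freqs, Zp


# ----------------------------------------------------------------------
# substitution effects
# ----------------------------------------------------------------------

@dataclass
class HaplotypeEffectModel:
    """Fitted haplotype substitution-effect model Y = X beta + Z u + e."""

    haplotype_labels: list[str]
    frequencies: np.ndarray
    effects: np.ndarray          # u, grams, sum-to-zero
    effect_se: np.ndarray
    beta: np.ndarray             # covariate effects including intercept
    fitted: np.ndarray
    residual_sd: float

    def table(self) -> pd.DataFrame:
        """Haplotype table sorted by effect, ascending."""
        out = pd.DataFrame({
            "haplotype": self.haplotype_labels,
            "frequency": self.frequencies,
            "effect_g": self.effects,
            "se_g": self.effect_se,
        })
        return out.sort_values("effect_g", ignore_index=True)


def substitution_effects(
    y: np.ndarray,
    Z: np.ndarray,
    covariates: np.ndarray | None = None,
    frequencies: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> HaplotypeEffectModel:
    """Least-squares haplotype substitution effects under a sum-to-zero
    contrast on u.

    Z must be full column rank after the one forced constraint (rows sum
    to 2, so one constraint is always needed); further rank deficiency
    raises an error naming the aliased columns.
    """
    y = np.asarray(y, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    n, k = Z.shape
    if k < 2:
        raise ValueError("need at least two haplotype classes")
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.column_stack([X, C])
    # sum-to-zero contrast: u = C @ u_free with C = [I; -1']
    Cmat = np.vstack([np.eye(k - 1), -np.ones(k - 1)])
    D = np.column_stack([X, Z @ Cmat])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # identify aliased haplotype columns via QR pivoting
        _, R = np.linalg.qr(D)
        diag = np.abs(np.diag(R))
        bad = [i - X.shape[1] for i in np.nonzero(diag < 1e-8 * diag.max())[0]
               if i >= X.shape[1]]
        names = [labels[i] if labels else str(i) for i in bad] or ["<unknown>"]
        raise ValueError(f"haplotype design is rank deficient; aliased columns: {names}")
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    fitted = D @ coef
    resid = y - fitted
    dof = n - D.shape[1]
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(D.T @ D)
    u_free = coef[X.shape[1]:]
    u = Cmat @ u_free
    cov_u = Cmat @ cov[X.shape[1]:, X.shape[1]:] @ Cmat.T
    se = np.sqrt(np.diag(cov_u))
    if frequencies is None:
        frequencies = Z.sum(axis=0) / (2.0 * n)
    if labels is None:
        labels = [f"hap{i}" for i in range(k)]
    return HaplotypeEffectModel(list(labels), np.asarray(frequencies, float),
                                u, se, coef[:X.shape[1]], fitted, float(np.sqrt(s2)))


# ----------------------------------------------------------------------
# backward elimination
# ----------------------------------------------------------------------

def _bh_reject(pvalues: np.ndarray, q: float, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg rejection mask at FDR q.

    ``m_total`` fixes the BH denominator at the full family size (the
    initial candidate count) so that repeated application during backward
    elimination keeps controlling the FDR of the whole search, not just
    of the shrinking current set.
    """
    m = pvalues.size
    m_total = m_total or m
    order = np.argsort(pvalues)
    thresh = q * (np.arange(1, m + 1)) / m_total
    passed = pvalues[order] <= thresh
    k = np.nonzero(passed)[0]
    mask = np.zeros(m, dtype=bool)
    if k.size:
        mask[order[: k[-1] + 1]] = True
    return mask


@dataclass
class EliminationResult:
    retained: list[str]                  # BESNP ids
    audit: pd.DataFrame                  # one row per elimination round


def backward_elimination(
    y: np.ndarray,
    candidates: np.ndarray,
    candidate_ids: list[str],
    candidate_positions: np.ndarray,
    background: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    fdr: float = 0.05,
) -> EliminationResult:
    """Multi-locus backward elimination of candidate SNPs at an FDR
    threshold.

    Each round fits one joint linear model (covariates + background SNPs,
    always retained + remaining candidates), computes per-candidate Wald
    p-values and applies Benjamini-Hochberg across the candidates.  If any
    candidate fails, the single largest-p candidate is dropped (tie -> the
    larger position) and the model refit; the loop stops when all
    remaining candidates pass.  Deterministic, and a fixed point of
    itself.  When the starting model has more predictors than samples the
    candidates are pre-screened by marginal p to n/2 predictors (logged).
    Perfectly collinear candidate pairs lose their later-position member
    before the first round (logged).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    G = np.asarray(candidates, dtype=float)
    pos = np.asarray(candidate_positions)
    ids = list(candidate_ids)
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.column_stack([X, C])
    if background is not None and np.asarray(background).size:
        B = np.asarray(background, dtype=float)
        if B.shape[0] != n:
            B = B.T
        X = np.column_stack([X, B])

    active = [j for j in range(G.shape[1]) if np.ptp(G[:, j]) > 0]
    for j in range(G.shape[1]):
        if j not in active:
            log.info("backward_elimination: dropping monomorphic candidate %s", ids[j])
    # drop perfectly collinear candidates (later position loses)
    if len(active) > 1:
        corr = np.corrcoef(G[:, active], rowvar=False)
        drop = set()
        for a in range(len(active)):
            for b in range(a + 1, len(active)):
                if active[b] in drop or active[a] in drop:
                    continue
                if abs(corr[a, b]) > 1.0 - 1e-12:
                    later = active[b] if pos[active[b]] >= pos[active[a]] else active[a]
                    drop.add(later)
                    log.info("backward_elimination: dropping %s, collinear with another candidate",
                             ids[later])
        active = [j for j in active if j not in drop]
    # pre-screen when saturated
    max_pred = n // 2
    if X.shape[1] + len(active) >= n and len(active) > max_pred - X.shape[1]:
        keep_n = max(1, max_pred - X.shape[1])
        marg = []
        for j in active:
            r = stats.linregress(G[:, j], y)
            marg.append(r.pvalue)
        order = np.argsort(marg)
        active = sorted(np.array(active)[order[:keep_n]].tolist())
        log.info("backward_elimination: pre-screened candidates to %d by marginal p", keep_n)

    audit_rows = []
    round_no = 0
    m_total = len(active)
    while active:
        D = np.column_stack([X, G[:, active]])
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ coef
        dof = n - D.shape[1]
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.pinv(D.T @ D)
        idx0 = X.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            tvals = coef[idx0:] / np.sqrt(np.diag(cov)[idx0:])
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
        pvals = np.where(np.isfinite(pvals), pvals, 1.0)   # undefined test -> drop first
        mask = _bh_reject(pvals, fdr, m_total)
        round_no += 1
        if mask.all():
            audit_rows.append((round_no, len(active), None, float(pvals.max())))
            break
        # drop the single worst candidate; ties -> larger position
        worst_p = pvals.max()
        worst = max((j for j, p in zip(active, pvals) if p == worst_p),
                    key=lambda j: pos[j])
        audit_rows.append((round_no, len(active), ids[worst], float(worst_p)))
        active.remove(worst)
    audit = pd.DataFrame(audit_rows, columns=["round", "n_candidates", "dropped", "max_p"])
    return EliminationResult([ids[j] for j in active], audit)
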