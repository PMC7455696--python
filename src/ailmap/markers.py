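"""Founder allele-frequency differentials, tiered informative-marker
selection, LD pruning and multiple-testing thresholds.

The fine-mapping design this package implements rests on markers that are
(nearly) fixed for alternative alleles in the two founder lines: tier-1
markers (|dAF| >= 0.95) discriminate founder-line origin for IBD painting,
a relaxed tier-2 set (|dAF| >= 0.75, thinned to >= 100 bp spacing) supports
dense haplotype association, and putatively functional SNPs
(missense/splice/UTR annotations) are admitted at a softer |dAF| >= 0.3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

ANNOT_CLASSES = ("none", "missense/splice", "utr")


@dataclass
class MarkerDiff:
    """Per-site founder allele-frequency differential."""

    site_id: str
    position: int
    af_popA: float
    af_popB: float
    annotation: str = "none"

    def __post_init__(self) -> None:
        for af in (self.af_popA, self.af_popB):
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"allele frequency {af} outside [0, 1]")
        if self.annotation not in ANNOT_CLASSES:
            raise ValueError(f"unknown annotation class {self.annotation!r}")

    @property
    def delta_af(self) -> float:
        return delta_af(self.af_popA, self.af_popB)


def delta_af(af_A: float, af_B: float) -> float:
    """Absolute founder allele-frequency differential |af_A - af_B|."""
    if not (0.0 <= af_A <= 1.0 and 0.0 <= af_B <= 1.0):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return abs(af_A - af_B)


def marker_diffs(
    gmA: GenotypeMatrix,
    gmB: GenotypeMatrix,
    annotations: dict[str, str] | None = None,
) -> list[MarkerDiff]:
    """Compute per-site differentials between two founder samples sharing a grid."""
    if not np.array_equal(gmA.positions, gmB.positions):
        raise ValueError("founder samples must share the same site grid")
    annotations = annotations or {}
    afA, afB = gmA.allele_freq(), gmB.allele_freq()
    out = []
    for j in range(gmA.n_sites):
        if np.isnan(afA[j]) or np.isnan(afB[j]):
            continue
        sid = str(gmA.ids[j])
        out.append(MarkerDiff(sid, int(gmA.positions[j]), float(afA[j]),
                              float(afB[j]), annotations.get(sid, "none")))
    return out


@dataclass
class MarkerSelection:
    """Tiered informative-marker selection result."""

    tier1: list[MarkerDiff]            # |dAF| >= tier1 threshold
    tier2: list[MarkerDiff]            # |dAF| >= tier2, spacing-thinned
    tier2_unspaced: list[MarkerDiff]   # before spacing (tier1 is a subset)
    annotated: list[MarkerDiff]        # functional classes at the soft threshold

    def table(self) -> pd.DataFrame:
        rows = []
        for tier, markers in (("tier1", self.tier1), ("tier2", self.tier2),
                              ("annotated", self.annotated)):
            for m in markers:
                rows.append((tier, m.site_id, m.position, m.af_popA, m.af_popB,
                             round(m.delta_af, 2), m.annotation))
        return pd.DataFrame(rows, columns=["tier", "site_id", "position",
                                           "af_popA", "af_popB", "delta_af",
                                           "annotation"])


def _thin_by_spacing(markers: list[MarkerDiff], spacing_bp: int) -> list[MarkerDiff]:
    """Greedy thinning: repeatedly admit the largest-dAF marker (tie ->
    smaller position) whose position is >= spacing_bp from every marker
    already kept."""
    order = sorted(markers, key=lambda m: (-m.delta_af, m.position))
    kept: list[MarkerDiff] = []
    for m in order:
        if all(abs(m.position - k.position) >= spacing_bp for k in kept):
            kept.append(m)
    return sorted(kept, key=lambda m: m.position)


def select_informative(
    diffs: list[MarkerDiff],
    tier1: float = 0.95,
    tier2: float = 0.75,
    annot_tier: float = 0.3,
    spacing_bp: int = 100,
) -> MarkerSelection:
    """Tiered selection of founder-informative markers.

    Tier 1 keeps sites with |dAF| >= ``tier1`` (origin-diagnostic).  Tier 2
    keeps sites with |dAF| >= ``tier2`` thinned so no two retained sites
    are closer than ``spacing_bp`` (the larger differential wins; ties go
    to the smaller position).  Annotated missense/splice/UTR sites are
    admitted separately at |dAF| >= ``annot_tier`` (excluded from tiers
    1-2 output unless they meet those thresholds themselves).
    """
    positions = [m.position for m in diffs]
    if positions != sorted(positions):
        raise ValueError("marker diffs must be sorted by position")
    t1 = [m for m in diffs if m.delta_af >= tier1]
    t2_raw = [m for m in diffs if m.delta_af >= tier2]
    t2 = _thin_by_spacing(t2_raw, spacing_bp)
    annot = [m for m in diffs
             if m.annotation != "none" and annot_tier <= m.delta_af < tier2]
    return MarkerSelection(t1, t2, t2_raw, annot)


# ----------------------------------------------------------------------
# LD
# ----------------------------------------------------------------------

def ld_r2(dosages_i: np.ndarray, dosages_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete samples; NaN for monomorphic input."""
    x = np.asarray(dosages_i, dtype=float)
    y = np.asarray(dosages_j, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _maf(dosage: np.ndarray) -> float:
    p = np.nanmean(dosage) / 2.0
    return min(p, 1.0 - p)


def ld_prune(
    gm: GenotypeMatrix,
    r2_max: float = 0.4,
    window_snps: int = 50,
    step_snps: int = 5,
) -> np.ndarray:
    """Sliding-window greedy LD pruning; returns kept site indices.

    Within each window, while any retained pair exceeds ``r2_max``, the
    member of the worst (highest-r^2) pair with the lower MAF is removed
    (tie -> the larger position).  The window then advances by
    ``step_snps``.  Deterministic, and invariant to sample ordering.
    """
    m = gm.n_sites
    dos = gm.dosages()
    # pruning works on mean-imputed dosages; identical to pairwise-complete
    # r^2 when there are no missing calls
    col_mean = np.nanmean(dos, axis=0)
    dos_f = np.where(np.isnan(dos), col_mean, dos)
    keep = np.ones(m, dtype=bool)
    start = 0
    while start < m:
        while True:
            idx = np.array([j for j in range(start, min(start + window_snps, m))
                            if keep[j] and np.ptp(dos_f[:, j]) > 0])
            if idx.size < 2:
                break
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(dos_f[:, idx], rowvar=False)
            r2 = np.nan_to_num(corr**2, nan=0.0)
            np.fill_diagonal(r2, 0.0)
            a, b = np.unravel_index(np.argmax(r2), r2.shape)
            if r2[a, b] <= r2_max:
                break
            i, j = int(idx[a]), int(idx[b])
            mi, mj = _maf(dos[:, i]), _maf(dos[:, j])
            if mi < mj:
                victim = i
            elif mj < mi:
                victim = j
            else:
                victim = max(i, j)   # tie: larger position goes
            keep[victim] = False
        if start + window_snps >= m:
            break
        start += step_snps
    return np.nonzero(keep)[0]


def n_independent_markers(gm: GenotypeMatrix, r2_max: float = 0.4) -> int:
    """Number of approximately independent markers: the count surviving
    LD pruning at ``r2_max`` (the threshold used for multiple-testing
    correction in the modeled design)."""
    return int(ld_prune(gm, r2_max=r2_max).size)


def bonferroni_threshold(alpha: float, n_independent: int) -> float:
    """Genome-wide significance threshold alpha / n_independent."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_independent < 1:
        raise ValueError("need at least one independent marker")
    return alpha / n_independent


def format_threshold(p: float, sig_digits: int = 3) -> str:
    """Render a threshold to the customary 3 significant digits."""
    if p <= 0:
        raise ValueError("threshold must be positive")
    exponent = math.floor(math.log10(p))
    mantissa = round(p / 10**exponent, sig_digits - 1)
    if mantissa >= 10:
        mantissa /= 10
        exponent += 1
    return f"{mantissa:.{sig_digits - 1}f}e{exponent:+03d}"
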