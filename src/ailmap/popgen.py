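"""Windowed diversity, differentiation and haplotype-based sweep statistics.

Implements the five scan statistics used to probe the focal QTL region for
selection signatures: nucleotide diversity (pi), Tajima's D, haplotype
diversity (H, Nei & Tajima), Fst (Hudson two-population estimator by
default, Weir-Cockerham available for cross-checking) and XP-EHH.

All scans take a :class:`~ailmap.genotypes.GenotypeMatrix` and return a
tidy table with columns ``chrom, start, end, statistic, value, n_sites``
(start/end 0-based half-open internally; the I/O layer emits 1-based
inclusive).  Undefined windows are reported with value NaN rather than
dropped, so scans over the same grid always align.

Sites with chromatid call rate below ``min_call_rate`` (default 0.9,
mirroring the global quality filter used throughout the study design this
package models) are excluded from every statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .sim import GeneticMap

DEFAULT_CALL_RATE = 0.9


def _window_grid(start: int, end: int, window_bp: int, step_bp: int):
    if step_bp <= 0 or window_bp < step_bp:
        raise ValueError("require window >= step > 0")
    s = start
    while s < end:
        yield s, min(s + window_bp, end)
        s += step_bp


def _usable_sites(gm: GenotypeMatrix, min_call_rate: float) -> np.ndarray:
    return np.nonzero(gm.call_rate() >= min_call_rate)[0]


def _per_site_pi(chromatids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean pairwise difference per site and called-chromatid count."""
    called = chromatids != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, chromatids, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, 2.0 * alt * (n - alt) / (n * (n - 1.0)), np.nan)
    return pi, n


def pi_scan(
    gm: GenotypeMatrix,
    window_bp: int = 500,
    step_bp: int = 250,
    region: tuple[int, int] | None = None,
    min_call_rate: float = DEFAULT_CALL_RATE,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity.

    Per window: average over accessible sites of the per-site mean pairwise
    difference (monomorphic sites contribute 0).  Windows without a single
    accessible site get value NaN.  The defaults are the fine-scale preset
    (500 bp window, 250 bp step); a coarse 50 kb / 25 kb preset suits
    chromosome-scale scans.
    """
    if 2 * gm.n_samples < 2:
        raise ValueError("pi requires at least 2 chromatids")
    usable = _usable_sites(gm, min_call_rate)
    pi_site, _ = _per_site_pi(gm.chromatids()[:, usable])
    pos = gm.positions[usable]
    lo = region[0] if region else int(gm.positions.min()) if gm.n_sites else 0
    hi = region[1] if region else int(gm.positions.max()) + 1 if gm.n_sites else 1
    rows = []
    for a, b in _window_grid(lo, hi, window_bp, step_bp):
        i, j = np.searchsorted(pos, [a, b])
        vals = pi_site[i:j]
        vals = vals[~np.isnan(vals)]
        value = float(vals.mean()) if vals.size else np.nan
        rows.append((gm.chrom, a, b, "pi", value, int(vals.size)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "statistic", "value", "n_sites"])


def tajima_constants(n: int) -> dict[str, float]:
    """The a1, a2, b1, b2, c1, c2, e1, e2 constants for sample size n."""
    if n < 2:
        raise ValueError("Tajima's D requires n >= 2 chromatids")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(
    gm: GenotypeMatrix,
    bin_bp: int = 25_000,
    region: tuple[int, int] | None = None,
    min_call_rate: float = DEFAULT_CALL_RATE,
) -> pd.DataFrame:
    """Tajima's D in non-overlapping bins (presets: 250 bp or 25 kb).

    D = (pi_total - S/a1) / sqrt(e1 S + e2 S (S - 1)) with the standard
    constants for the chromatid count; bins with S = 0 are reported NaN
    (undefined), never 0.
    """
    n = 2 * gm.n_samples
    if n < 2:
        raise ValueError("Tajima's D requires n >= 2 chromatids")
    const = tajima_constants(n)
    usable = _usable_sites(gm, min_call_rate)
    chromatids = gm.chromatids()[:, usable]
    pi_site, n_called = _per_site_pi(chromatids)
    freq = gm.allele_freq()[usable]
    seg = (freq > 0) & (freq < 1)
    pos = gm.positions[usable]
    lo = region[0] if region else int(gm.positions.min()) if gm.n_sites else 0
    hi = region[1] if region else int(gm.positions.max()) + 1 if gm.n_sites else 1
    rows = []
    for a, b in _window_grid(lo, hi, bin_bp, bin_bp):
        i, j = np.searchsorted(pos, [a, b])
        S = int(seg[i:j].sum())
        if S == 0:
            rows.append((gm.chrom, a, b, "tajimas_d", np.nan, int(j - i)))
            continue
        pi_total = float(np.nansum(pi_site[i:j]))
        var = const["e1"] * S + const["e2"] * S * (S - 1)
        d = (pi_total - S / const["a1"]) / np.sqrt(var)
        rows.append((gm.chrom, a, b, "tajimas_d", float(d), int(j - i)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "statistic", "value", "n_sites"])


def hap_diversity_bin(chromatids: np.ndarray) -> float:
    """Nei & Tajima haplotype diversity of one bin's chromatid strings.

    H = n/(n-1) * (1 - sum p_i^2) over distinct-haplotype frequencies;
    chromatids with any missing call in the bin are excluded.
    """
    keep = ~np.any(chromatids == MISSING, axis=1)
    chromatids = chromatids[keep]
    n = chromatids.shape[0]
    if n < 2:
        return np.nan
    _, counts = np.unique(chromatids, axis=0, return_counts=True)
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def hap_diversity(
    gm: GenotypeMatrix,
    bin_bp: int = 2000,
    region: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Haplotype diversity (H) in non-overlapping bins (default 2 kb)."""
    if not gm.phased:
        raise ValueError("haplotype diversity requires phased input")
    if 2 * gm.n_samples < 2:
        raise ValueError("requires >= 2 chromatids")
    chromatids = gm.chromatids()
    lo = region[0] if region else int(gm.positions.min()) if gm.n_sites else 0
    hi = region[1] if region else int(gm.positions.max()) + 1 if gm.n_sites else 1
    rows = []
    for a, b in _window_grid(lo, hi, bin_bp, bin_bp):
        i, j = np.searchsorted(gm.positions, [a, b])
        value = hap_diversity_bin(chromatids[:, i:j]) if j > i else np.nan
        rows.append((gm.chrom, a, b, "hap_diversity", value, int(j - i)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "statistic", "value", "n_sites"])


# ----------------------------------------------------------------------
# Fst
# ----------------------------------------------------------------------

def _hudson_components(gmA: GenotypeMatrix, gmB: GenotypeMatrix):
    """Per-site numerator and denominator of Hudson's Fst."""
    pA, pB = gmA.allele_freq(), gmB.allele_freq()
    hA = gmA.chromatids()
    hB = gmB.chromatids()
    nA = (hA != MISSING).sum(axis=0).astype(float)
    nB = (hB != MISSING).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((pA - pB) ** 2
               - pA * (1 - pA) / (nA - 1)
               - pB * (1 - pB) / (nB - 1))
        den = pA * (1 - pB) + pB * (1 - pA)
    return num, den


def _wc_components(gmA: GenotypeMatrix, gmB: GenotypeMatrix):
    """Per-site Weir-Cockerham theta components (two populations,
    haploid-chromatid samples), for cross-checking the Hudson default."""
    pA, pB = gmA.allele_freq(), gmB.allele_freq()
    nA = (gmA.chromatids() != MISSING).sum(axis=0).astype(float)
    nB = (gmB.chromatids() != MISSING).sum(axis=0).astype(float)
    n_bar = (nA + nB) / 2.0
    r = 2.0
    nc = (nA + nB - (nA**2 + nB**2) / (nA + nB)) / (r - 1.0)
    p_bar = (nA * pA + nB * pB) / (nA + nB)
    s2 = (nA * (pA - p_bar) ** 2 + nB * (pB - p_bar) ** 2) / ((r - 1.0) * n_bar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / nc) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2)
    return a, a + b


def fst(
    gmA: GenotypeMatrix,
    gmB: GenotypeMatrix,
    window_bp: int | None = None,
    estimator: str = "hudson",
    min_call_rate: float = DEFAULT_CALL_RATE,
    region: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Fst between two populations, per site or in windows.

    With ``window_bp=None`` one row per site is returned; otherwise the
    ratio-of-averages over non-overlapping windows (default preset in the
    modeled study: per-site, or 20 kb bins).  Sites monomorphic in the
    pooled sample are undefined per site and excluded from window averages.
    """
    if not np.array_equal(gmA.positions, gmB.positions):
        raise ValueError("populations must share the same site grid")
    if estimator == "hudson":
        num, den = _hudson_components(gmA, gmB)
    elif estimator == "wc":
        num, den = _wc_components(gmA, gmB)
    else:
        raise ValueError(f"unknown Fst estimator {estimator!r}")
    ok = ((gmA.call_rate() >= min_call_rate) & (gmB.call_rate() >= min_call_rate)
          & np.isfinite(num) & np.isfinite(den) & (den > 0))
    cols = ["chrom", "start", "end", "statistic", "value", "n_sites"]
    if window_bp is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(ok, num / np.where(den > 0, den, np.nan), np.nan)
        return pd.DataFrame({
            "chrom": gmA.chrom,
            "start": gmA.positions,
            "end": gmA.positions + 1,
            "statistic": "fst",
            "value": vals,
            "n_sites": 1,
        })[cols]
    lo = region[0] if region else int(gmA.positions.min())
    hi = region[1] if region else int(gmA.positions.max()) + 1
    rows = []
    for a, b in _window_grid(lo, hi, window_bp, window_bp):
        i, j = np.searchsorted(gmA.positions, [a, b])
        sel = ok[i:j]
        if sel.sum() == 0:
            rows.append((gmA.chrom, a, b, "fst", np.nan, 0))
            continue
        value = float(num[i:j][sel].sum() / den[i:j][sel].sum())
        rows.append((gmA.chrom, a, b, "fst", value, int(sel.sum())))
    return pd.DataFrame(rows, columns=cols)


# ----------------------------------------------------------------------
# EHH / XP-EHH
# ----------------------------------------------------------------------

def ehh_curve(haplotypes: np.ndarray, core_idx: int) -> tuple[np.ndarray, np.ndarray]:
    """EHH of a haplotype sample at every marker, extending from the core.

    At marker j, EHH is the probability that two random chromatids are
    identical over all markers between the core and j inclusive:
    sum_h C(n_h, 2) / C(n, 2) over distinct extended haplotypes h.
    Returns (marker indices, EHH values) ordered left-to-right across the
    whole marker set; EHH is non-increasing away from the core.
    """
    n, m = haplotypes.shape
    if n < 2:
        raise ValueError("EHH requires >= 2 chromatids")
    denom = n * (n - 1) / 2.0
    ehh = np.empty(m)

    def extend(direction: int):
        # group chromatids by identity, refining marker by marker
        groups = {}
        for i in range(n):
            groups.setdefault(haplotypes[i, core_idx], []).append(i)
        idx = core_idx
        while 0 <= idx < m:
            if idx != core_idx:
                new_groups = {}
                for key, members in groups.items():
                    if len(members) < 2:
                        continue
                    for i in members:
                        new_groups.setdefault(key + (haplotypes[i, idx],), []).append(i)
                groups = new_groups
            else:
                groups = {(k,): v for k, v in groups.items()}
            ehh[idx] = sum(len(v) * (len(v) - 1) / 2.0 for v in groups.values()) / denom
            idx += direction

    extend(+1)
    extend(-1)
    return np.arange(m), ehh


def _ihh(haplotypes: np.ndarray, core_idx: int, cM: np.ndarray,
         truncate_ehh: float = 0.05) -> float:
    """Integrated EHH (both directions) over genetic distance, trapezoid
    rule, truncated once EHH falls below ``truncate_ehh``."""
    _, ehh = ehh_curve(haplotypes, core_idx)
    total = 0.0
    for sl in (slice(core_idx, None, 1), slice(core_idx, None, -1)):
        e = ehh[sl]
        x = np.abs(cM[sl] - cM[core_idx])
        below = np.nonzero(e < truncate_ehh)[0]
        stop = below[0] if below.size else e.size
        if stop >= 2:
            total += float(np.trapezoid(e[:stop], x[:stop]))
    return total


def xpehh(
    gmA: GenotypeMatrix,
    gmB: GenotypeMatrix,
    core_position: int,
    gmap: GeneticMap,
    truncate_ehh: float = 0.05,
) -> float:
    """Raw (unstandardized) XP-EHH at one core site: ln(iHH_A / iHH_B).

    The core site must be polymorphic in the pooled sample; EHH curves use
    all chromatids of each population (the core allele is part of the
    extended haplotype), integrated over genetic distance with truncation
    at EHH < ``truncate_ehh``.  Returns NaN when iHH_B has no decay
    support.  Use :func:`xpehh_scan` for the scan-level z-normalization.
    """
    for gm in (gmA, gmB):
        if not gm.phased:
            raise ValueError("XP-EHH requires phased haplotypes")
    if not np.array_equal(gmA.positions, gmB.positions):
        raise ValueError("populations must share the same site grid")
    core = int(np.nonzero(gmA.positions == core_position)[0][0]) \
        if core_position in gmA.positions else None
    if core is None:
        raise ValueError(f"core position {core_position} not on the grid")
    pooled = np.vstack([gmA.chromatids(), gmB.chromatids()])
    freq = pooled[:, core].mean()
    if freq <= 0 or freq >= 1:
        raise ValueError("core site is monomorphic in the pooled sample")
    cM = gmap.bp_to_cM(gmA.positions)
    ihh_a = _ihh(gmA.chromatids(), core, cM, truncate_ehh)
    ihh_b = _ihh(gmB.chromatids(), core, cM, truncate_ehh)
    if ihh_b == 0.0 or ihh_a == 0.0:
        return np.nan
    return float(np.log(ihh_a / ihh_b))


def xpehh_scan(
    gmA: GenotypeMatrix,
    gmB: GenotypeMatrix,
    gmap: GeneticMap,
    truncate_ehh: float = 0.05,
) -> pd.DataFrame:
    """XP-EHH at every pooled-polymorphic site, plus z-normalized scores.

    The ``value`` column holds the scan-normalized score
    (raw - mean) / SD over defined raw scores; ``raw`` keeps the
    unstandardized log-ratio.
    """
    pooled_freq = (gmA.allele_freq() * gmA.n_samples + gmB.allele_freq() * gmB.n_samples) \
        / (gmA.n_samples + gmB.n_samples)
    raws = np.full(gmA.n_sites, np.nan)
    for j in range(gmA.n_sites):
        if 0 < pooled_freq[j] < 1:
            raws[j] = xpehh(gmA, gmB, int(gmA.positions[j]), gmap, truncate_ehh)
    defined = np.isfinite(raws)
    norm = np.full_like(raws, np.nan)
    if defined.sum() >= 2 and np.nanstd(raws) > 0:
        norm[defined] = (raws[defined] - raws[defined].mean()) / raws[defined].std()
    out = pd.DataFrame({
        "chrom": gmA.chrom,
        "start": gmA.positions,
        "end": gmA.positions + 1,
        "statistic": "xpehh",
        "value": norm,
        "raw": raws,
        "n_sites": 1,
    })
    return out
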