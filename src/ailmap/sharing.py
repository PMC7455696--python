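"""Multi-breed haplotype-sharing scan for Q regions.

The scan asks where, across a candidate interval, high-body-weight breeds
share the growth-increasing founder ("Q") haplotype that low-weight breeds
lack.  The region is tiled with 2-kb bins anchored at the scan start; in
each bin the Q haplotype is defined as the modal haplotype of the
reference founder group, and the signed frequency differential
dAF_Q = freq(Q | high group) - freq(Q | low group) is computed.  Maximal
runs of adjacent bins with dAF_Q at or above the threshold (0.4 in the
modeled design) are merged into named Q regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class BinHaplotypes:
    """Distinct haplotypes of one bin with per-group frequencies."""

    start: int
    end: int
    n_sites: int
    haplotypes: list[str]
    group_freqs: dict[str, np.ndarray]   # group -> frequencies over `haplotypes`

    def freq(self, group: str, haplotype: str) -> float:
        try:
            i = self.haplotypes.index(haplotype)
        except ValueError:
            return 0.0
        return float(self.group_freqs[group][i])


def _bin_strings(chromatids: np.ndarray) -> list[str]:
    return ["".join("." if a == MISSING else str(int(a)) for a in row)
            for row in chromatids]


def bin_haplotypes(
    gm: GenotypeMatrix,
    groups: dict[str, str] | pd.Series,
    bin_bp: int = 2000,
    region: tuple[int, int] | None = None,
) -> list[BinHaplotypes]:
    """Per-bin haplotype frequencies by group.

    Bins tile the region from its start (0-based grid, emitted 1-based by
    the I/O layer).  Chromatids with a missing call in a bin are excluded
    from that bin's counts.  Bins without SNPs are returned with
    ``n_sites = 0`` and empty frequency tables; the scan skips them.
    Every sample must carry a group label.
    """
    if not gm.phased:
        raise ValueError("haplotype-sharing scan requires phased input")
    groups = pd.Series(groups)
    missing = [s for s in gm.samples if s not in groups.index]
    if missing:
        raise ValueError(f"samples without a group label: {missing[:5]}")
    sample_groups = np.repeat([groups[s] for s in gm.samples], 2)
    chromatids = gm.chromatids()
    if region is None:
        region = (int(gm.positions.min()), int(gm.positions.max()) + 1)
    out: list[BinHaplotypes] = []
    group_names = sorted(set(sample_groups))
    for a in range(region[0], region[1], bin_bp):
        b = min(a + bin_bp, region[1])
        i, j = np.searchsorted(gm.positions, [a, b])
        if j <= i:
            out.append(BinHaplotypes(a, b, 0, [], {g: np.array([]) for g in group_names}))
            continue
        sub = chromatids[:, i:j]
        complete = ~np.any(sub == MISSING, axis=1)
        strings = np.array(_bin_strings(sub))
        haps = sorted(set(strings[complete]))
        freqs = {}
        for g in group_names:
            sel = complete & (sample_groups == g)
            n = int(sel.sum())
            if n == 0:
                freqs[g] = np.zeros(len(haps))
                continue
            counts = pd.Series(strings[sel]).value_counts()
            freqs[g] = np.array([counts.get(h, 0) / n for h in haps])
        out.append(BinHaplotypes(a, b, int(j - i), haps, freqs))
    return out


def q_delta_af(
    bin_: BinHaplotypes,
    reference_group: str,
    high_group: str,
    low_group: str,
) -> tuple[float, str]:
    """Signed Q-haplotype frequency differential for one bin.

    The Q haplotype is the modal haplotype of the reference founder group
    (ties broken by the lexicographically smallest string); the return is
    (freq(Q | high) - freq(Q | low), Q string).  NaN when the reference
    group has no complete chromatid in the bin.
    """
    if bin_.n_sites == 0:
        return np.nan, ""
    ref = bin_.group_freqs.get(reference_group)
    if ref is None or ref.size == 0 or ref.sum() == 0:
        return np.nan, ""
    best = ref.max()
    q = min(h for h, f in zip(bin_.haplotypes, ref) if f == best)
    return bin_.freq(high_group, q) - bin_.freq(low_group, q), q


@dataclass
class QRegion:
    """Merged run of adjacent bins with dAF_Q at or above the threshold."""

    name: str
    start: int
    end: int
    bin_starts: list[int]
    bin_deltas: list[float]

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def max_delta(self) -> float:
        return max(self.bin_deltas)

    @property
    def mean_delta(self) -> float:
        return float(np.mean(self.bin_deltas))


def merge_q_regions(
    bins: list[BinHaplotypes],
    deltas: list[float],
    threshold: float = 0.4,
) -> list[QRegion]:
    """Merge adjacent passing bins into Q regions, named Q1..Qk left to
    right.  SNP-less (or undefined-dAF) bins break adjacency."""
    regions: list[QRegion] = []
    cur: QRegion | None = None
    for b, d in zip(bins, deltas):
        passing = np.isfinite(d) and d >= threshold and b.n_sites > 0
        if passing:
            if cur is not None and cur.end == b.start:
                cur.end = b.end
                cur.bin_starts.append(b.start)
                cur.bin_deltas.append(float(d))
            else:
                cur = QRegion(name="", start=b.start, end=b.end,
                              bin_starts=[b.start], bin_deltas=[float(d)])
                regions.append(cur)
        else:
            cur = None
    for i, r in enumerate(regions, start=1):
        r.name = f"Q{i}"
    return regions


def sharing_scan(
    gm: GenotypeMatrix,
    groups: dict[str, str] | pd.Series,
    reference_group: str,
    high_group: str = "high",
    low_group: str = "low",
    bin_bp: int = 2000,
    threshold: float = 0.4,
    region: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, list[QRegion]]:
    """End-to-end Q-region scan: bin, score, merge.

    Returns the per-bin table (chrom, start, end, n_sites, q_haplotype,
    delta_af_q) and the merged Q regions.
    """
    bins = bin_haplotypes(gm, groups, bin_bp, region)
    rows = []
    deltas = []
    for b in bins:
        d, q = q_delta_af(b, reference_group, high_group, low_group)
        deltas.append(d)
        rows.append((gm.chrom, b.start, b.end, b.n_sites, q, d))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites",
                                        "q_haplotype", "delta_af_q"])
    return table, merge_q_regions(bins, deltas, threshold)
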