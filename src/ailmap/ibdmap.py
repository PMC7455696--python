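"""Founder-line origin painting of AIL chromatids from diagnostic markers.

Tier-1 informative markers are (nearly) fixed for alternative alleles in
the two founder lines, so each allele can be assigned to one line.  At a
homozygous marker both chromatids of an individual share the implied
origin; at a heterozygous marker one chromatid carries each origin, and
the phase across markers is resolved by minimizing the total number of
origin switches over both chromatids (dynamic programming over the two
phase choices per heterozygous site).  This parsimony rule reflects the
biology of a deep intercross: with a handful of expected crossovers per
region, the painting with the fewest switches is overwhelmingly the most
likely one.

Chromatid origins are then collapsed to breed-level recombination
breakpoints, per-block founder-origin diplotype classes, and unpaired
(Welch) t-tests of the trait against block origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

ORIGIN_A, ORIGIN_B, ORIGIN_UNKNOWN = 0, 1, -1
_LABELS = {ORIGIN_A: "A", ORIGIN_B: "B", ORIGIN_UNKNOWN: "unknown"}

# chromatid-pair states for the phase DP, in deterministic tie-break order
_STATES_HOM_A = ((ORIGIN_A, ORIGIN_A),)
_STATES_HOM_B = ((ORIGIN_B, ORIGIN_B),)
_STATES_HET = ((ORIGIN_A, ORIGIN_B), (ORIGIN_B, ORIGIN_A))


@dataclass
class PaintingSet:
    """Marker-level origin assignments for a cohort.

    ``origins`` has shape (n_individuals, 2, n_markers) with codes
    0 = founder line A, 1 = line B, -1 = unknown.
    """

    ids: list[str]
    marker_positions: np.ndarray
    region: tuple[int, int]
    origins: np.ndarray

    def segments(self, individual_idx: int, chromatid: int) -> list[tuple[int, int, str]]:
        """Run-length segments for one chromatid, tiling the region.

        Segment boundaries at origin switches use the midpoint of the
        flanking marker interval (0-based half-open coordinates).
        """
        o = self.origins[individual_idx, chromatid]
        pos = self.marker_positions
        start, end = self.region
        if np.all(o == ORIGIN_UNKNOWN):
            return [(start, end, "unknown")]
        segs = []
        seg_start = start
        for j in range(1, o.size):
            if o[j] != o[j - 1]:
                mid = int((pos[j - 1] + pos[j]) // 2)
                segs.append((seg_start, mid, _LABELS[int(o[j - 1])]))
                seg_start = mid
        segs.append((seg_start, end, _LABELS[int(o[-1])]))
        return segs

    def table(self, chrom: str = "1") -> pd.DataFrame:
        rows = []
        for i, ind in enumerate(self.ids):
            for c in range(2):
                for s, e, lab in self.segments(i, c):
                    rows.append((chrom, s, e, f"{ind}|{c}", lab))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "chromatid", "origin"])

    def n_switches(self, individual_idx: int) -> int:
        o = self.origins[individual_idx]
        return int(sum(np.sum(o[c, 1:] != o[c, :-1]) for c in range(2)))


def _phase_dp(a_counts: np.ndarray) -> np.ndarray:
    """Minimum-switch origin assignment for one individual.

    ``a_counts`` holds, per informative marker, the number of line-A
    alleles (0/1/2) or -1 when missing.  Returns (2, m) origin codes.
    """
    m = a_counts.size
    obs = [j for j in range(m) if a_counts[j] >= 0]
    out = np.full((2, m), ORIGIN_UNKNOWN, dtype=np.int8)
    if not obs:
        return out

    def states(j):
        c = a_counts[j]
        return _STATES_HOM_A if c == 2 else _STATES_HOM_B if c == 0 else _STATES_HET

    # forward pass
    costs = [{s: 0 for s in states(obs[0])}]
    for j in obs[1:]:
        layer = {}
        for s in states(j):
            layer[s] = min(prev_cost + (s[0] != p[0]) + (s[1] != p[1])
                           for p, prev_cost in costs[-1].items())
        costs.append(layer)
    # backtrack, preferring earlier enumeration order on ties
    last = costs[-1]
    cur = min(last, key=lambda s: (last[s], _STATES_HET.index(s) if s in _STATES_HET else 0))
    assign = [cur]
    for step in range(len(obs) - 1, 0, -1):
        layer = costs[step - 1]
        cur = min(layer, key=lambda p: (layer[p] + (assign[-1][0] != p[0]) + (assign[-1][1] != p[1]),
                                        _STATES_HET.index(p) if p in _STATES_HET else 0))
        assign.append(cur)
    assign.reverse()
    for j, s in zip(obs, assign):
        out[:, j] = s
    # fill missing markers from the left flank (leading gaps from the right)
    for c in range(2):
        row = out[c]
        last_seen = None
        for j in range(m):
            if row[j] != ORIGIN_UNKNOWN:
                last_seen = row[j]
            elif last_seen is not None:
                row[j] = last_seen
        first = next(j for j in range(m) if row[j] != ORIGIN_UNKNOWN)
        row[:first] = row[first]
    return out


def _suppress_short_runs(origins: np.ndarray, min_support: int) -> int:
    """Relabel runs shorter than ``min_support`` markers to the flanking
    consensus (both flanks agreeing, or the single flank at an edge);
    returns the number of relabeled runs."""
    if min_support <= 1:
        return 0
    relabeled = 0
    m = origins.size
    j = 0
    while j < m:
        k = j
        while k < m and origins[k] == origins[j]:
            k += 1
        run_len = k - j
        left = origins[j - 1] if j > 0 else None
        right = origins[k] if k < m else None
        if run_len < min_support:
            target = None
            if left is not None and right is not None and left == right:
                target = left
            elif left is None and right is not None:
                target = right
            elif right is None and left is not None:
                target = left
            if target is not None and target != origins[j]:
                origins[j:k] = target
                relabeled += 1
        j = k
    return relabeled


def paint(
    gm: GenotypeMatrix,
    founder_key: np.ndarray,
    region: tuple[int, int] | None = None,
    min_support: int = 2,
) -> PaintingSet:
    """Paint founder-line origin along every chromatid.

    Parameters
    ----------
    gm : GenotypeMatrix
        Genotypes at tier-1 informative markers (may be unphased).
    founder_key : array of int
        Per marker, the allele (0/1) diagnostic of founder line A.
    region : (start, end), optional
        Painted interval; defaults to the marker span padded to the
        outermost markers.
    min_support : int
        Runs supported by fewer consecutive markers are relabeled to the
        flanking consensus (a genotyping-noise guard; 1 disables).
    """
    founder_key = np.asarray(founder_key)
    if founder_key.size != gm.n_sites:
        raise ValueError("founder key length must match marker count")
    if region is None:
        region = (int(gm.positions[0]), int(gm.positions[-1]) + 1)
    h = gm.haplotypes
    is_a = (h == founder_key[None, :, None])
    a_counts = np.where(np.any(h == MISSING, axis=2), -1, is_a.sum(axis=2)).astype(np.int8)
    origins = np.empty((gm.n_samples, 2, gm.n_sites), dtype=np.int8)
    n_relabeled = 0
    for i in range(gm.n_samples):
        origins[i] = _phase_dp(a_counts[i])
        for c in range(2):
            if not np.all(origins[i, c] == ORIGIN_UNKNOWN):
                n_relabeled += _suppress_short_runs(origins[i, c], min_support)
    if n_relabeled:
        log.info("paint: relabeled %d short origin runs (min_support=%d)",
                 n_relabeled, min_support)
    return PaintingSet(list(gm.samples), gm.positions.copy(), region, origins)


# ----------------------------------------------------------------------
# blocks
# ----------------------------------------------------------------------

@dataclass
class BlockSet:
    """Breed-level breakpoints and per-individual per-block diplotypes."""

    ids: list[str]
    breakpoints: list[int]                  # bp, midpoint convention
    blocks: list[tuple[int, int]]           # 0-based half-open, tiling the region
    block_origins: np.ndarray               # (n, 2, n_blocks) origin codes
    recombinant: np.ndarray                 # (n,) bool

    def diplotype(self, individual_idx: int, block: int) -> str:
        o = sorted(self.block_origins[individual_idx, :, block])
        if ORIGIN_UNKNOWN in o:
            return "recombinant-ambiguous"
        return {(0, 0): "AA", (0, 1): "AB", (1, 1): "BB"}[tuple(o)]

    def class_table(self) -> pd.DataFrame:
        data = {f"block{b + 1}": [self.diplotype(i, b) for i in range(len(self.ids))]
                for b in range(len(self.blocks))}
        out = pd.DataFrame(data, index=self.ids)
        out.insert(0, "recombinant", self.recombinant)
        return out


def call_blocks(ps: PaintingSet) -> BlockSet:
    """Collapse paintings to breed-level breakpoints and diplotype classes.

    Breakpoints are the union over chromatids of observed origin-switch
    midpoints; the intervals they delimit partition the region, and every
    chromatid has a constant origin within each block.  Individuals whose
    chromatids never switch are 'unrecombined' (AA/AB/BB across the whole
    region); the rest are recombinant.
    """
    pos = ps.marker_positions
    switch_mids = set()
    n = len(ps.ids)
    recombinant = np.zeros(n, dtype=bool)
    for i in range(n):
        for c in range(2):
            o = ps.origins[i, c]
            sw = np.nonzero((o[1:] != o[:-1]) & (o[1:] != ORIGIN_UNKNOWN)
                            & (o[:-1] != ORIGIN_UNKNOWN))[0]
            if sw.size:
                recombinant[i] = True
                for j in sw:
                    switch_mids.add(int((pos[j] + pos[j + 1]) // 2))
    breakpoints = sorted(switch_mids)
    edges = [ps.region[0]] + breakpoints + [ps.region[1]]
    blocks = list(zip(edges[:-1], edges[1:]))
    block_origins = np.empty((n, 2, len(blocks)), dtype=np.int8)
    for b, (s, e) in enumerate(blocks):
        in_block = (pos >= s) & (pos < e)
        for i in range(n):
            for c in range(2):
                vals = ps.origins[i, c, in_block]
                vals = vals[vals != ORIGIN_UNKNOWN]
                if vals.size == 0:
                    block_origins[i, c, b] = ORIGIN_UNKNOWN
                else:
                    # constant within a block by construction; majority as guard
                    block_origins[i, c, b] = int(round(vals.mean()))
    return BlockSet(list(ps.ids), breakpoints, blocks, block_origins, recombinant)


@dataclass
class BlockTest:
    block: int
    p_value: float
    mean_A: float
    mean_B: float
    n_A: int
    n_B: int
    genotype_means: pd.DataFrame     # class -> mean, sd, n over all individuals


def block_ttest(
    bs: BlockSet,
    phenotype: dict[str, float] | pd.Series,
    block: int,
    recombinants_only: bool = True,
) -> BlockTest:
    """Welch unpaired t-test of the trait against block origin.

    Chromatids (of recombinant individuals by default) are grouped by
    their origin within the block and each contributes its carrier's
    phenotype; the test contrasts the line-A-origin and line-B-origin
    groups.  Per-block three-genotype-class means +/- SD over all
    individuals are reported alongside.  Groups with fewer than two
    chromatids yield an undefined (NaN) p-value.
    """
    pheno = pd.Series(phenotype)
    groups = {ORIGIN_A: [], ORIGIN_B: []}
    for i, ind in enumerate(bs.ids):
        if recombinants_only and not bs.recombinant[i]:
            continue
        if ind not in pheno.index or not np.isfinite(pheno[ind]):
            continue
        for c in range(2):
            o = int(bs.block_origins[i, c, block])
            if o in groups:
                groups[o].append(float(pheno[ind]))
    a, b = np.array(groups[ORIGIN_A]), np.array(groups[ORIGIN_B])
    if a.size >= 2 and b.size >= 2:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        p = np.nan
    rows = []
    for cls in ("AA", "AB", "BB"):
        vals = np.array([pheno[ind] for i, ind in enumerate(bs.ids)
                         if bs.diplotype(i, block) == cls
                         and ind in pheno.index and np.isfinite(pheno[ind])])
        rows.append((cls, vals.mean() if vals.size else np.nan,
                     vals.std(ddof=1) if vals.size > 1 else np.nan, vals.size))
    gmeans = pd.DataFrame(rows, columns=["class", "mean", "sd", "n"])
    return BlockTest(block, p,
                     float(a.mean()) if a.size else np.nan,
                     float(b.mean()) if b.size else np.nan,
                     int(a.size), int(b.size), gmeans)
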