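"""Forward simulator of a two-line advanced intercross and a multi-breed panel.

The simulator emulates the mapping design behind the package: two divergent
but outbred founder populations (a fast-growing commercial broiler line and
a slow-growing native breed), each segregating several ancestral haplotypes
across a ~3 Mb focal region; an F0 -> Fk random-mating advanced intercross
line (AIL) with recombination at a constant cM/Mb rate; a weight-like trait
controlled by a multi-locus additive QTL plus sex and batch effects; and a
panel of unrelated breeds split into high- and low-weight groups that share
subsets of the growth-increasing ("Q") haplotype.

Every individual carries, besides its two phased haplotypes, the *true*
founder-line origin mosaic of each chromatid, so downstream inference
(IBD painting, block calling, Q-region scans) can be scored against truth.

Recombination uses a Poisson crossover count on the genetic length of the
region with uniform breakpoint placement (no interference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

# origin painting: ordered list of (start_bp, end_bp, label), half-open,
# tiling [region_start, region_end)
Painting = list[tuple[int, int, str]]


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Constant-rate genetic map over one region.

    The default rate of 2.8 cM/Mb is the focal-chromosome estimate for the
    chicken intercross this package models; the default region is the
    3.1 Mb QTL interval at the distal end of chromosome 1.
    """

    rate_cM_per_Mb: float = 2.8
    region_start_bp: int = 168_600_000
    region_end_bp: int = 171_700_000

    def __post_init__(self) -> None:
        if self.rate_cM_per_Mb < 0:
            raise ValueError("map rate must be non-negative")
        if self.region_end_bp <= self.region_start_bp:
            raise ValueError("region end must exceed region start")

    @property
    def length_bp(self) -> int:
        return self.region_end_bp - self.region_start_bp

    @property
    def length_cM(self) -> float:
        return self.length_bp / 1e6 * self.rate_cM_per_Mb

    @property
    def length_morgans(self) -> float:
        return self.length_cM / 100.0

    def bp_to_cM(self, bp) -> np.ndarray:
        """Genetic position (cM from region start) of physical positions."""
        return (np.asarray(bp, dtype=float) - self.region_start_bp) / 1e6 * self.rate_cM_per_Mb


def snp_grid(gmap: GeneticMap, spacing_bp: int = 2000) -> np.ndarray:
    """Fixed SNP grid over the region, one site per ``spacing_bp``.

    The default spacing (2 kb over 3.1 Mb -> 1,550 sites) guarantees every
    2-kb haplotype-sharing bin contains a site.
    """
    return np.arange(gmap.region_start_bp, gmap.region_end_bp, spacing_bp, dtype=np.int64)


@dataclass
class FounderPoolSpec:
    """Ancestral haplotype pool of one founder line.

    ``haplotype_pool`` is an int8 array of shape (n_haplotypes, n_sites)
    over the simulated SNP grid; ``pool_weights`` are the sampling
    probabilities of each ancestral haplotype within the line.
    """

    label: str
    haplotype_pool: np.ndarray
    pool_weights: np.ndarray

    def __post_init__(self) -> None:
        self.haplotype_pool = np.asarray(self.haplotype_pool, dtype=np.int8)
        self.pool_weights = np.asarray(self.pool_weights, dtype=float)
        if self.haplotype_pool.ndim != 2 or self.haplotype_pool.shape[0] == 0:
            raise ValueError(f"pool {self.label!r} is empty")
        if self.pool_weights.shape[0] != self.haplotype_pool.shape[0]:
            raise ValueError("pool_weights length must match haplotype count")
        if np.any(self.pool_weights < 0) or np.any(self.pool_weights > 1):
            raise ValueError("pool weights must lie in [0, 1]")
        if abs(self.pool_weights.sum() - 1.0) > 1e-9:
            raise ValueError("pool weights must sum to 1")

    @property
    def n_sites(self) -> int:
        return self.haplotype_pool.shape[1]


@dataclass
class QTLLocus:
    position_bp: int
    effect_g: float          # additive effect per copy of the high allele, grams
    high_allele: int = 1


@dataclass
class QTLArchitecture:
    """Multi-locus additive architecture of the weight-like trait.

    Defaults give a two-locus QTL with effects on the order of one residual
    SD in total, a male-larger sex dimorphism typical of broiler-type
    chickens, small hatch-batch offsets, and a residual SD of 100 g.
    """

    loci: list[QTLLocus] = field(default_factory=lambda: [
        QTLLocus(169_240_000, 120.0, 1),
        QTLLocus(169_650_000, 90.0, 1),
    ])
    baseline_g: float = 700.0
    sex_effect_g: float = 250.0           # added for males
    batch_effects_g: tuple = (0.0, 25.0, -20.0, 10.0)
    residual_sd_g: float = 100.0

    def __post_init__(self) -> None:
        if self.residual_sd_g < 0:
            raise ValueError("residual SD must be non-negative")


@dataclass
class PedigreeIndividual:
    """A simulated animal with phased genomes and true origin mosaics."""

    id: str
    generation: int
    sire_id: str | None
    dam_id: str | None
    sex: str                         # 'M' or 'F'
    batch: int
    haplotypes: np.ndarray           # (2, n_sites) int8
    paintings: list[Painting]        # true founder-line origin per chromatid
    phenotype: float | None = None
    background: np.ndarray | None = None   # (n_background_loci, 2) int8, unlinked


# ----------------------------------------------------------------------
# painting algebra
# ----------------------------------------------------------------------

def _compress(painting: Painting) -> Painting:
    """Merge adjacent segments with identical labels."""
    out: Painting = []
    for seg in painting:
        if out and out[-1][2] == seg[2] and out[-1][1] == seg[0]:
            out[-1] = (out[-1][0], seg[1], seg[2])
        else:
            out.append(tuple(seg))
    return out


def _slice_painting(painting: Painting, a: int, b: int) -> Painting:
    """Restrict a painting to [a, b)."""
    out: Painting = []
    for s, e, lab in painting:
        s2, e2 = max(s, a), min(e, b)
        if s2 < e2:
            out.append((s2, e2, lab))
    return out


def check_painting(painting: Painting, start: int, end: int) -> None:
    """Raise if a painting does not tile [start, end) without overlap."""
    if not painting:
        raise ValueError("empty painting")
    if painting[0][0] != start or painting[-1][1] != end:
        raise ValueError("painting does not span the region")
    for (s0, e0, _), (s1, e1, _) in zip(painting, painting[1:]):
        if e0 != s1:
            raise ValueError("painting segments do not tile")
        if e0 <= s0 or e1 <= s1:
            raise ValueError("degenerate painting segment")


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------

def make_founders(
    poolA: FounderPoolSpec,
    poolB: FounderPoolSpec,
    nA: int,
    nB: int,
    seed,
    gmap: GeneticMap | None = None,
    n_batches: int = 4,
) -> list[PedigreeIndividual]:
    """Draw F0 founders, each haplotype i.i.d. from its line's pool.

    Sexes alternate within each line so both sexes are always present.
    Each chromatid's origin painting is a single segment carrying the
    line label.
    """
    if poolA.n_sites != poolB.n_sites:
        raise ValueError("founder pools have mismatched haplotype lengths")
    if nA < 1 or nB < 1:
        raise ValueError("need at least one founder per line")
    gmap = gmap or GeneticMap()
    rng = as_rng(seed)
    founders: list[PedigreeIndividual] = []
    for pool, n in ((poolA, nA), (poolB, nB)):
        k = pool.haplotype_pool.shape[0]
        for i in range(n):
            picks = rng.choice(k, size=2, p=pool.pool_weights)
            haps = pool.haplotype_pool[picks].copy()
            painting = [(gmap.region_start_bp, gmap.region_end_bp, pool.label)]
            founders.append(PedigreeIndividual(
                id=f"{pool.label}_{i}",
                generation=0,
                sire_id=None,
                dam_id=None,
                sex="M" if i % 2 == 0 else "F",
                batch=int(rng.integers(n_batches)),
                haplotypes=haps,
                paintings=[list(painting), list(painting)],
            ))
    return founders


def meiosis(
    parent: PedigreeIndividual,
    gmap: GeneticMap,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, Painting]:
    """One gamete: Poisson crossover count, uniform breakpoint placement.

    Crossover count ~ Poisson(genetic length in Morgans); breakpoints are
    uniform on the region; the gamete alternates parental chromatids at
    the breakpoints, and the origin painting is spliced accordingly.
    """
    if gmap.length_bp <= 0:
        raise ValueError("zero-length region")
    n_cx = int(rng.poisson(gmap.length_morgans))
    first = int(rng.integers(2))
    if n_cx == 0:
        return parent.haplotypes[first].copy(), list(parent.paintings[first])
    breaks = np.sort(rng.integers(gmap.region_start_bp + 1, gmap.region_end_bp, size=n_cx))
    bounds = np.concatenate(([gmap.region_start_bp], breaks, [gmap.region_end_bp]))
    gamete = np.empty_like(parent.haplotypes[0])
    painting: Painting = []
    which = first
    for a, b in zip(bounds[:-1], bounds[1:]):
        if a == b:
            which = 1 - which
            continue
        lo, hi = np.searchsorted(positions, [a, b])
        gamete[lo:hi] = parent.haplotypes[which][lo:hi]
        painting.extend(_slice_painting(parent.paintings[which], int(a), int(b)))
        which = 1 - which
    return gamete, _compress(painting)


def simulate_ail(
    founders: list[PedigreeIndividual],
    generation_sizes: list[int],
    gmap: GeneticMap,
    positions: np.ndarray,
    seed,
    n_batches: int = 4,
) -> dict[int, list[PedigreeIndividual]]:
    """Breed an AIL: F1 by interline crosses, later generations by random
    non-self mating within the previous generation.

    Returns a dict generation number -> individuals; generation 0 is the
    founders as given.  Fully reproducible for a fixed seed.
    """
    if not generation_sizes:
        raise ValueError("generation_sizes must be non-empty")
    rng = as_rng(seed)
    pedigree: dict[int, list[PedigreeIndividual]] = {0: list(founders)}
    lines = sorted({ind.paintings[0][0][2] for ind in founders})

    for g, size in enumerate(generation_sizes, start=1):
        prev = pedigree[g - 1]
        males = [i for i in prev if i.sex == "M"]
        females = [i for i in prev if i.sex == "F"]
        if len(males) < 1 or len(females) < 1:
            raise ValueError(f"generation {g - 1} lacks individuals of one sex")
        if g >= 2 and (len(males) < 2 or len(females) < 2) and size > 1:
            raise ValueError(f"generation {g - 1} has <2 individuals of a sex")
        children = []
        for i in range(size):
            if g == 1 and len(lines) == 2:
                # interline cross: sire and dam from different founder lines
                la, lb = (lines if rng.integers(2) == 0 else lines[::-1])
                sires = [m for m in males if m.paintings[0][0][2] == la]
                dams = [f for f in females if f.paintings[0][0][2] == lb]
                if not sires or not dams:
                    sires = [m for m in males if m.paintings[0][0][2] == lb]
                    dams = [f for f in females if f.paintings[0][0][2] == la]
                if not sires or not dams:
                    raise ValueError("interline F1 cross impossible: a line lacks one sex")
            else:
                sires, dams = males, females
            sire = sires[int(rng.integers(len(sires)))]
            dam = dams[int(rng.integers(len(dams)))]
            hap_s, paint_s = meiosis(sire, gmap, positions, rng)
            hap_d, paint_d = meiosis(dam, gmap, positions, rng)
            children.append(PedigreeIndividual(
                id=f"F{g}_{i}",
                generation=g,
                sire_id=sire.id,
                dam_id=dam.id,
                sex="M" if i % 2 == 0 else "F",
                batch=int(rng.integers(n_batches)),
                haplotypes=np.stack([hap_s, hap_d]),
                paintings=[paint_s, paint_d],
            ))
        pedigree[g] = children
    return pedigree


def simulate_background_loci(
    pedigree: dict[int, list[PedigreeIndividual]],
    n_loci: int,
    seed,
    founder_freq: float = 0.5,
) -> None:
    """Drop unlinked biallelic loci through the pedigree (free recombination).

    Emulates the polygenic background residing on other chromosomes:
    founder alleles are Bernoulli(``founder_freq``) in both lines and each
    child inherits one random allele per locus from each parent.  Results
    are stored on each individual's ``background`` field.
    """
    rng = as_rng(seed)
    by_id: dict[str, PedigreeIndividual] = {}
    for g in sorted(pedigree):
        for ind in pedigree[g]:
            if ind.generation == 0:
                ind.background = (rng.random((n_loci, 2)) < founder_freq).astype(np.int8)
            else:
                sire = by_id[ind.sire_id]
                dam = by_id[ind.dam_id]
                pick_s = rng.integers(2, size=n_loci)
                pick_d = rng.integers(2, size=n_loci)
                ind.background = np.stack([
                    sire.background[np.arange(n_loci), pick_s],
                    dam.background[np.arange(n_loci), pick_d],
                ], axis=1).astype(np.int8)
            by_id[ind.id] = ind


def simulate_phenotypes(
    individuals: list[PedigreeIndividual],
    arch: QTLArchitecture,
    positions: np.ndarray,
    seed,
    background_effects: np.ndarray | None = None,
) -> pd.DataFrame:
    """Weight-like trait: baseline + additive QTL + sex + batch + noise.

    phenotype = baseline + sum_loci dosage(high allele) * effect
              + sex offset + batch offset [+ background term] + N(0, sd).

    ``background_effects`` gives per-locus additive effects for the
    unlinked background loci from :func:`simulate_background_loci`.
    Phenotypes are written back onto the individuals and returned as a
    table (id, generation, sex, batch, phenotype_g).
    """
    rng = as_rng(seed)
    pos_idx = []
    for locus in arch.loci:
        hits = np.nonzero(positions == locus.position_bp)[0]
        if hits.size == 0:
            raise ValueError(f"QTL position {locus.position_bp} is not on the SNP grid")
        pos_idx.append(int(hits[0]))
    rows = []
    for ind in individuals:
        value = arch.baseline_g
        for locus, j in zip(arch.loci, pos_idx):
            dosage = int((ind.haplotypes[:, j] == locus.high_allele).sum())
            value += dosage * locus.effect_g
        if ind.sex == "M":
            value += arch.sex_effect_g
        value += arch.batch_effects_g[ind.batch % len(arch.batch_effects_g)]
        if background_effects is not None:
            if ind.background is None:
                raise ValueError("background effects given but individual has no background loci")
            value += float(ind.background.sum(axis=1) @ background_effects)
        value += rng.normal(0.0, arch.residual_sd_g)
        ind.phenotype = float(value)
        rows.append((ind.id, ind.generation, ind.sex, ind.batch, ind.phenotype))
    return pd.DataFrame(rows, columns=["id", "generation", "sex", "batch", "phenotype_g"])


def pedigree_relationship_matrix(
    pedigree: dict[int, list[PedigreeIndividual]],
    individuals: list[PedigreeIndividual] | None = None,
) -> np.ndarray:
    """Additive (numerator) relationship matrix by the tabular method.

    Founders are treated as unrelated and non-inbred.  For any additive
    architecture transmitted through this pedigree the genetic covariance
    is Vg * A, which makes A the natural GRM stand-in for a genome-wide
    marker panel when only one region is simulated.  Returns the submatrix
    for ``individuals`` (default: the last generation).
    """
    ordered: list[PedigreeIndividual] = []
    for g in sorted(pedigree):
        ordered.extend(pedigree[g])
    index = {ind.id: i for i, ind in enumerate(ordered)}
    n = len(ordered)
    A = np.zeros((n, n))
    for i, ind in enumerate(ordered):
        if ind.sire_id is None:
            A[i, i] = 1.0
        else:
            s, d = index[ind.sire_id], index[ind.dam_id]
            A[i, i] = 1.0 + 0.5 * A[s, d]
            for j in range(i):
                A[i, j] = A[j, i] = 0.5 * (A[j, s] + A[j, d])
    if individuals is None:
        individuals = pedigree[max(pedigree)]
    idx = np.array([index[ind.id] for ind in individuals])
    return A[np.ix_(idx, idx)]


# ----------------------------------------------------------------------
# pool construction and the multi-breed panel
# ----------------------------------------------------------------------

def make_divergent_pools(
    positions: np.ndarray,
    seed,
    n_hap_A: int = 4,
    n_hap_B: int = 4,
    frac_diagnostic: float = 0.05,
    q_private_intervals: list[tuple[int, int]] | None = None,
    qtl_positions: list[int] | None = None,
    labels: tuple[str, str] = ("HQLA", "HB"),
) -> tuple[FounderPoolSpec, FounderPoolSpec]:
    """Build two divergent mosaic founder pools over a SNP grid.

    A fraction of sites are line-diagnostic (fixed 1 in line A, 0 in
    line B), mimicking near-complete allele-frequency divergence between a
    selected broiler line and an unselected native breed.  Inside each
    ``q_private_interval`` the first line-A haplotype (the canonical
    growth-increasing "Q" haplotype) carries private derived alleles absent
    from every other ancestral haplotype.  Remaining sites get independent
    line-specific allele frequencies drawn from a U-shaped Beta(0.4, 0.4),
    giving a realistic spread of allele-frequency differentials.
    """
    rng = as_rng(seed)
    m = positions.shape[0]
    diagnostic = rng.random(m) < frac_diagnostic
    pA = rng.beta(0.4, 0.4, size=m)
    pB = rng.beta(0.4, 0.4, size=m)
    hapsA = (rng.random((n_hap_A, m)) < pA).astype(np.int8)
    hapsB = (rng.random((n_hap_B, m)) < pB).astype(np.int8)
    hapsA[:, diagnostic] = 1
    hapsB[:, diagnostic] = 0
    # divergent QTL-allele fixation: the growth-increasing allele (1) is
    # fixed in line A and absent in line B, the premise of founder-line
    # IBD mapping
    for p in (qtl_positions or []):
        j = np.nonzero(positions == p)[0]
        if j.size == 0:
            raise ValueError(f"QTL position {p} is not on the SNP grid")
        hapsA[:, j[0]] = 1
        hapsB[:, j[0]] = 0
    for a, b in (q_private_intervals or []):
        in_iv = (positions >= a) & (positions < b)
        hapsA[:, in_iv] = 0
        hapsA[0, in_iv] = 1
        hapsB[:, in_iv] = 0
    wA = np.full(n_hap_A, 1.0 / n_hap_A)
    wB = np.full(n_hap_B, 1.0 / n_hap_B)
    if n_hap_A > 1:
        # directional selection in line A drove the growth-increasing Q
        # haplotype to majority frequency; it must outnumber the combined
        # alternatives for "modal haplotype of the reference group" to
        # mean Q in any bin
        wA = np.array([0.7] + [0.3 / (n_hap_A - 1)] * (n_hap_A - 1))
    return (FounderPoolSpec(labels[0], hapsA, wA),
            FounderPoolSpec(labels[1], hapsB, wB))


@dataclass
class BreedSpec:
    """One breed of the multi-breed panel."""

    name: str
    group: str              # 'high' or 'low' body-weight group
    n: int                  # individuals
    q_carrier_freq: float   # chromatid probability of carrying the Q segment
                            # across each planted shared interval


def simulate_breed_panel(
    poolA: FounderPoolSpec,
    poolB: FounderPoolSpec,
    breeds: list[BreedSpec],
    q_intervals: list[tuple[int, int]],
    positions: np.ndarray,
    seed,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Unrelated multi-breed panel sharing Q sub-haplotypes.

    Each chromatid is a background draw from the combined ancestral pool
    (both lines, equal weight); within each planted interval it carries the
    canonical Q haplotype's alleles with the breed's carrier frequency.
    High-weight breeds are given high carrier frequencies and low-weight
    breeds low ones, emulating shared selection on Q sub-segments.
    """
    rng = as_rng(seed)
    m = positions.shape[0]
    q_hap = poolA.haplotype_pool[0]
    pool = np.vstack([poolA.haplotype_pool, poolB.haplotype_pool])
    weights = np.concatenate([poolA.pool_weights * 0.5, poolB.pool_weights * 0.5])
    iv_masks = [(positions >= a) & (positions < b) for a, b in q_intervals]

    haps = np.empty((sum(b.n for b in breeds), m, 2), dtype=np.int8)
    rows = []
    i = 0
    for breed in breeds:
        for _ in range(breed.n):
            for c in range(2):
                chromatid = pool[rng.choice(pool.shape[0], p=weights)].copy()
                for mask in iv_masks:
                    if rng.random() < breed.q_carrier_freq:
                        chromatid[mask] = q_hap[mask]
                haps[i, :, c] = chromatid
            rows.append((f"{breed.name}_{_}", breed.name, breed.group))
            i += 1
    samples = [r[0] for r in rows]
    gm = GenotypeMatrix("1", positions, np.array([f"s{p}" for p in positions]),
                        samples, haps, phased=True)
    groups = pd.DataFrame(rows, columns=["sample", "breed", "group"])
    return gm, groups


# ----------------------------------------------------------------------
# export
# ----------------------------------------------------------------------

def pedigree_to_genotypes(
    individuals: list[PedigreeIndividual],
    positions: np.ndarray,
    chrom: str = "1",
) -> GenotypeMatrix:
    """Stack individuals into a phased :class:`GenotypeMatrix`."""
    haps = np.stack([ind.haplotypes.T for ind in individuals])  # (n, m, 2)
    ids = np.array([f"s{p}" for p in positions])
    return GenotypeMatrix(chrom, positions, ids, [i.id for i in individuals],
                          haps, phased=True)


def paintings_table(individuals: list[PedigreeIndividual], chrom: str = "1") -> pd.DataFrame:
    """True origin mosaics as a BED-like table (0-based half-open),
    chromatid-suffixed ids."""
    rows = []
    for ind in individuals:
        for c, painting in enumerate(ind.paintings):
            for s, e, lab in painting:
                rows.append((chrom, s, e, f"{ind.id}|{c}", lab))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "chromatid", "origin"])
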