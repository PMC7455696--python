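"""Core genotype container shared by every scan in the package.

Positions are stored 0-based internally; text formats (VCF/TSV) are
converted at the I/O boundary.  Alleles are coded 0 (REF) / 1 (ALT) with
-1 marking a missing call on a chromatid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Diploid genotypes with positions, the substrate of every scan.

    Parameters
    ----------
    chrom : str
        Contig name, e.g. ``"1"`` for GGA1.
    positions : np.ndarray
        0-based site positions, strictly increasing, shape ``(n_sites,)``.
    ids : np.ndarray
        Site identifiers, shape ``(n_sites,)``.
    samples : list of str
        Sample names, length ``n_samples``.
    haplotypes : np.ndarray
        ``int8`` array of shape ``(n_samples, n_sites, 2)``; the last axis
        indexes the two chromatids.  When ``phased`` is False the split of
        a heterozygote over the two chromatid slots is arbitrary and only
        the dosage is meaningful.
    phased : bool
        True when chromatid rows represent real haplotypes.
    """

    chrom: str
    positions: np.ndarray
    ids: np.ndarray
    samples: list[str]
    haplotypes: np.ndarray
    phased: bool = True

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ids = np.asarray(self.ids)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[2] != 2:
            raise ValueError("haplotypes must have shape (n_samples, n_sites, 2)")
        if self.haplotypes.shape[1] != self.positions.shape[0]:
            raise ValueError("positions and haplotypes disagree on n_sites")
        if len(self.samples) != self.haplotypes.shape[0]:
            raise ValueError("samples and haplotypes disagree on n_samples")
        if self.positions.size > 1 and np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def dosages(self) -> np.ndarray:
        """ALT-allele dosage per sample/site as float, NaN where any
        chromatid call is missing."""
        h = self.haplotypes.astype(float)
        h[self.haplotypes == MISSING] = np.nan
        return h.sum(axis=2)

    def chromatids(self) -> np.ndarray:
        """All chromatids stacked as ``(2 * n_samples, n_sites)``.

        Sample *i* contributes rows ``2 i`` and ``2 i + 1``.
        """
        return self.haplotypes.transpose(0, 2, 1).reshape(-1, self.n_sites)

    def allele_freq(self) -> np.ndarray:
        """ALT frequency per site over non-missing chromatids (NaN if none)."""
        h = self.chromatids()
        called = h != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, h, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / n, np.nan)

    def call_rate(self) -> np.ndarray:
        """Fraction of chromatids called per site."""
        h = self.chromatids()
        return (h != MISSING).mean(axis=0)

    # ------------------------------------------------------------------
    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.chrom,
            self.positions[idx],
            self.ids[idx],
            list(self.samples),
            self.haplotypes[:, idx, :],
            self.phased,
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.chrom,
            self.positions,
            self.ids,
            [self.samples[i] for i in idx],
            self.haplotypes[idx, :, :],
            self.phased,
        )

    def region(self, start_bp: int, end_bp: int) -> "GenotypeMatrix":
        """Subset to sites with ``start_bp <= pos < end_bp`` (0-based)."""
        mask = (self.positions >= start_bp) & (self.positions < end_bp)
        return self.take_sites(np.nonzero(mask)[0])

    def sample_index(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[n] for n in names], dtype=np.intp)


def concat_samples(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two matrices over the same site grid along the sample axis."""
    if not np.array_equal(a.positions, b.positions):
        raise ValueError("matrices must share the same site grid")
    dup = set(a.samples) & set(b.samples)
    if dup:
        raise ValueError(f"duplicate sample names: {sorted(dup)[:5]}")
    return GenotypeMatrix(
        a.chrom, a.positions, a.ids, list(a.samples) + list(b.samples),
        np.concatenate([a.haplotypes, b.haplotypes], axis=0),
        a.phased and b.phased,
    )
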