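"""Format I/O: VCF, phenotype/covariate TSV, BED-like painting tables.

Coordinate conventions: VCF POS and TSV positions are 1-based inclusive on
disk and converted to the package's internal 0-based coordinates on read;
BED output is 0-based half-open.  Reading uses cyvcf2; writing emits
minimal VCF v4.2 with a contig header and GT-only FORMAT.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


def read_vcf(path, region: str | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    ``region`` is a 1-based "chrom:start-end" filter (tabix-style; works
    without an index by streaming).  Multi-allelic records are skipped
    with a log message.  The phased flag is True only when every
    heterozygous call in the file is phased; missing calls are preserved.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    want = None
    if region:
        chrom, _, span = region.partition(":")
        if span:
            a, _, b = span.partition("-")
            want = (chrom, int(a), int(b))
        else:
            want = (chrom, 1, 2**62)
    chroms, positions, ids, rows, phased_flags = [], [], [], [], []
    n_multi = 0
    for v in vcf:
        if want is not None:
            if v.CHROM != want[0] or not (want[1] <= v.POS <= want[2]):
                continue
        if len(v.ALT) > 1:
            n_multi += 1
            continue
        chroms.append(v.CHROM)
        positions.append(v.POS - 1)
        ids.append(v.ID if v.ID not in (None, ".") else f"s{v.POS - 1}")
        gt = np.array(v.genotypes, dtype=object)
        alleles = np.array([[a if a is not None and a >= 0 else MISSING for a in g[:2]]
                            for g in v.genotypes], dtype=np.int8)
        rows.append(alleles)
        het = alleles[:, 0] != alleles[:, 1]
        ph = np.array([g[2] for g in v.genotypes], dtype=bool)
        phased_flags.append(bool(np.all(ph[het])) if het.any() else True)
    if n_multi:
        log.info("read_vcf: skipped %d multi-allelic records", n_multi)
    if not positions:
        return GenotypeMatrix(want[0] if want else "1", np.empty(0, dtype=np.int64),
                              np.empty(0, dtype=object), samples,
                              np.empty((len(samples), 0, 2), dtype=np.int8), True)
    order = np.argsort(positions, kind="stable")
    haps = np.stack(rows, axis=1)[:, order, :]
    phased = all(phased_flags)
    if not phased:
        log.warning("read_vcf: mixed or unphased genotypes; phased flag set False")
    return GenotypeMatrix(chroms[0], np.array(positions)[order],
                          np.array(ids, dtype=object)[order], samples, haps, phased)


def write_vcf(gm: GenotypeMatrix, path, contig_length: int | None = None) -> None:
    """Write a GenotypeMatrix as minimal VCF v4.2 (GT only).

    Phased genotypes use the '|' separator, unphased '/'; internal 0-based
    positions are emitted as 1-based POS.  Alleles are written as REF=A,
    ALT=G placeholders since the simulator tracks only 0/1 states.
    """
    sep = "|" if gm.phased else "/"
    length = contig_length or (int(gm.positions.max()) + 2 if gm.n_sites else 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={gm.chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j in range(gm.n_sites):
            calls = []
            for i in range(gm.n_samples):
                a, b = gm.haplotypes[i, j]
                sa = "." if a == MISSING else str(int(a))
                sb = "." if b == MISSING else str(int(b))
                calls.append(f"{sa}{sep}{sb}")
            fh.write(f"{gm.chrom}\t{int(gm.positions[j]) + 1}\t{gm.ids[j]}"
                     f"\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_paintings(table: pd.DataFrame, path) -> None:
    """BED-like truth/inferred painting table (0-based half-open)."""
    table.to_csv(path, sep="\t", index=False)


def write_bed(intervals: list[tuple], path, names: list[str] | None = None,
              chrom: str = "1") -> None:
    """Plain BED (0-based half-open) for Q regions and blocks."""
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(intervals):
            name = names[i] if names else f"iv{i + 1}"
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def write_scan(table: pd.DataFrame, path) -> None:
    """Scan TSV with 1-based inclusive start/end columns on disk."""
    out = table.copy()
    if "start" in out.columns:
        out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_group_labels(path) -> pd.Series:
    """TSV with columns sample, group (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["group"].values, index=df["sample"].values)


def read_founder_key(path) -> pd.DataFrame:
    """TSV with columns site_id, position (1-based), allele_A."""
    df = pd.read_csv(path, sep="\t")
    df["position"] = df["position"] - 1
    return df


def ensure_exists(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input path does not exist: {p}")
    return p
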