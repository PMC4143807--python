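"""VCF/BED input, minor-allele dosage coding, and per-gene genotype matrices.

Dosages count copies of the *minor* allele (0/1/2 for aa, Aa, AA with A the
minor allele in the analyzed sample). Columns are oriented so the stored
frequency is always <= 0.5; monomorphic columns are dropped; missing
genotypes are imputed to the column mean dosage so downstream covariance
estimation never has to drop individuals.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

# cyvcf2 gt_types codes
_HOM_REF, _HET, _UNKNOWN, _HOM_ALT = 0, 1, 2, 3
_ALT_DOSAGE = {_HOM_REF: 0.0, _HET: 1.0, _UNKNOWN: np.nan, _HOM_ALT: 2.0}


class BedFormatError(ValueError):
    """Malformed BED line (too few columns, or start >= end)."""


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int                 # 1-based, VCF convention
    ref: str
    alt: str
    maf: float               # minor-allele frequency in the analyzed sample, <= 0.5
    minor_is_alt: bool

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"oriented MAF must lie in [0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class GeneRegion:
    """Named interval in BED convention (0-based, half-open)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise BedFormatError(f"region {self.name!r}: start {self.start} >= end {self.end}")

    def contains(self, pos: int) -> bool:
        """Whether a 1-based variant position falls in this region."""
        return self.start < pos <= self.end


@dataclass
class GenotypeMatrix:
    """Individuals x variants minor-allele dosage matrix for one gene region."""

    ids: list[str]
    variants: list[Variant]
    dosage: np.ndarray  # float (n, m); mean-imputed where genotypes were missing

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.ids)} ids x {len(self.variants)} variants"
            )
        self._index = {iid: i for i, iid in enumerate(self.ids)}

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def rows(self, ids: Iterable[str]) -> np.ndarray:
        missing = [i for i in ids if i not in self._index]
        if missing:
            raise ValueError(f"ids absent from genotype matrix: {missing[:5]}")
        return np.array([self._index[i] for i in ids], dtype=int)


def load_regions(path: str | Path) -> list[GeneRegion]:
    """Read gene regions from a BED file (>=4 columns), in file order.

    Overlapping regions are permitted: a variant may belong to several genes.
    """
    regions: list[GeneRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith(("#", "track", "browser")):
                continue
            if len(fields) < 4:
                raise BedFormatError(f"{path}, line {lineno}: expected >=4 columns")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start >= end:
                raise BedFormatError(
                    f"{path}, line {lineno}: start {start} >= end {end}"
                )
            regions.append(GeneRegion(name=name, chrom=chrom, start=start, end=end))
    return regions


def finalize_matrix(
    ids: Sequence[str],
    raw_variants: Sequence[tuple[str, int, str, str]],
    alt_dosage: np.ndarray,
) -> GenotypeMatrix:
    """Orient raw ALT-allele dosages to the minor allele and filter columns.

    Per column: the minor allele is whichever allele has sample frequency
    <= 0.5 (a tie at exactly 0.5 counts the ALT allele as minor); monomorphic
    or zero-variance columns are dropped; missing entries are imputed to the
    column mean dosage computed over observed genotypes.
    """
    alt_dosage = np.asarray(alt_dosage, dtype=float)
    n = len(ids)
    keep_variants: list[Variant] = []
    keep_cols: list[np.ndarray] = []
    for j, (chrom, pos, ref, alt) in enumerate(raw_variants):
        col = alt_dosage[:, j].copy()
        observed = ~np.isnan(col)
        n_obs = int(observed.sum())
        if n_obs == 0:
            continue
        alt_freq = col[observed].sum() / (2.0 * n_obs)
        minor_is_alt = alt_freq <= 0.5
        if not minor_is_alt:
            col = 2.0 - col
        maf = alt_freq if minor_is_alt else 1.0 - alt_freq
        if maf == 0.0 or np.nanstd(col) == 0.0:
            continue  # monomorphic in the analyzed sample
        col[~observed] = col[observed].mean()
        keep_variants.append(
            Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, maf=float(maf),
                    minor_is_alt=bool(minor_is_alt))
        )
        keep_cols.append(col)
    dosage = np.column_stack(keep_cols) if keep_cols else np.zeros((n, 0))
    return GenotypeMatrix(ids=list(ids), variants=keep_variants, dosage=dosage)


def _open_vcf(path: str | Path, ids: Sequence[str]):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    missing = [i for i in ids if i not in set(vcf.samples)]
    if missing:
        raise ValueError(f"requested ids absent from VCF {path}: {missing[:10]}")
    vcf.set_samples(list(ids))
    # permutation from VCF sample order (subset) to requested order
    order = {s: k for k, s in enumerate(vcf.samples)}
    perm = np.array([order[i] for i in ids], dtype=int)
    return vcf, perm


def extract_all_regions(
    vcf_path: str | Path,
    regions: Sequence[GeneRegion],
    ids: Sequence[str],
) -> dict[str, GenotypeMatrix]:
    """Single-pass extraction of every region's genotype matrix from a VCF.

    Works on plain or bgzipped VCF without requiring an index. Multi-allelic
    records are skipped with a warning (the 0/1/2 coding is biallelic).
    Returns a dict keyed by region name; regions with no polymorphic variant
    map to an empty matrix.
    """
    trees: dict[str, IntervalTree] = {}
    for region in regions:
        trees.setdefault(region.chrom, IntervalTree())[region.start:region.end] = region.name
    collected: dict[str, list] = {r.name: [] for r in regions}

    vcf, perm = _open_vcf(vcf_path, ids)
    for v in vcf:
        if len(v.ALT) != 1:
            log.warning("skipping multi-allelic record %s:%d", v.CHROM, v.POS)
            continue
        tree = trees.get(v.CHROM)
        if tree is None:
            continue
        hits = tree[v.POS - 1]  # BED half-open: include start < pos <= end
        if not hits:
            continue
        gt = np.array([_ALT_DOSAGE[t] for t in v.gt_types], dtype=float)[perm]
        record = (v.CHROM, v.POS, v.REF, v.ALT[0], gt)
        for hit in hits:
            collected[hit.data].append(record)
    vcf.close()

    out: dict[str, GenotypeMatrix] = {}
    for region in regions:
        recs = collected[region.name]
        if recs:
            raw = [(c, p, r, a) for c, p, r, a, _ in recs]
            alt = np.column_stack([g for *_, g in recs])
        else:
            raw, alt = [], np.zeros((len(ids), 0))
        out[region.name] = finalize_matrix(ids, raw, alt)
    return out


def extract_gene_matrix(
    vcf_path: str | Path, region: GeneRegion, ids: Sequence[str]
) -> GenotypeMatrix:
    """Genotype matrix for a single gene region (see :func:`extract_all_regions`)."""
    return extract_all_regions(vcf_path, [region], ids)[region.name]


def allele_counts(
    matrix: GenotypeMatrix, variant_index: int, group: Iterable[str]
) -> tuple[float, float]:
    """(minor, major) allele counts in a group for one variant column.

    Mean-imputed dosages contribute fractionally, so counts are reals.
    """
    rows = matrix.rows(group)
    if rows.size == 0:
        raise ValueError("group must be non-empty")
    minor = float(matrix.dosage[rows, variant_index].sum())
    return minor, 2.0 * rows.size - minor


def write_vcf(
    path: str | Path,
    ids: Sequence[str],
    matrices: Iterable[GenotypeMatrix],
) -> None:
    """Serialize genotype matrices to a minimal plain-text VCF 4.2 file.

    Dosages must be integral (no imputed fractions); duplicate
    (chrom, pos, ref, alt) records across overlapping matrices are written
    once. Genotypes are emitted unphased on the REF/ALT scale, undoing the
    minor-allele orientation.
    """
    records: dict[tuple[str, int, str, str], np.ndarray] = {}
    chrom_order: list[str] = []
    for matrix in matrices:
        if matrix.ids != list(ids):
            raise ValueError("all matrices must share the requested id order")
        for j, var in enumerate(matrix.variants):
            key = (var.chrom, var.pos, var.ref, var.alt)
            if key in records:
                continue
            col = matrix.dosage[:, j]
            rounded = np.rint(col)
            if not np.allclose(col, rounded, atol=1e-9):
                raise ValueError(
                    f"variant {var.chrom}:{var.pos} has non-integral (imputed) "
                    "dosages and cannot be serialized to VCF"
                )
            alt_count = rounded if var.minor_is_alt else 2.0 - rounded
            records[key] = alt_count.astype(int)
            if var.chrom not in chrom_order:
                chrom_order.append(var.chrom)

    gt_string = {0: "0/0", 1: "0/1", 2: "1/1"}
    chrom_rank = {c: k for k, c in enumerate(chrom_order)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=famseq-assoc\n")
        for chrom in chrom_order:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        for key in sorted(records, key=lambda k: (chrom_rank[k[0]], k[1], k[2], k[3])):
            chrom, pos, ref, alt = key
            gts = "\t".join(gt_string[int(c)] for c in records[key])
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated phenotype table with header ``fid iid pheno``.

    Phenotype coding: 2 = case, 1 = control, anything else = missing.
    """
    table = pd.read_csv(path, sep="\t", dtype={"fid": str, "iid": str})
    required = {"fid", "iid", "pheno"}
    if not required.issubset(table.columns):
        raise ValueError(f"phenotype table must have columns {sorted(required)}")
    return table


def phenotype_partition(table: pd.DataFrame) -> tuple[list[str], list[str]]:
    """(case ids, control ids) from a phenotype table; missing are excluded."""
    pheno = pd.to_numeric(table["pheno"], errors="coerce")
    cases = table.loc[pheno == 2, "iid"].tolist()
    controls = table.loc[pheno == 1, "iid"].tolist()
    return cases, controls
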