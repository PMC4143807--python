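"""Genome-scan driver: run the four tests over every gene region and tabulate.

The scan computes the familial correction factor once per case/control
partition (it does not depend on genotype), fits one :class:`GeneAssociation`
per gene in input-region order, and emits a deterministic tab-separated
table, one row per gene. Significance counting, Bonferroni thresholds and
gene-set overlaps operate on that table.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .association import GeneAssociation
from .genotypes import (
    GeneRegion,
    GenotypeMatrix,
    extract_all_regions,
    phenotype_partition,
    read_phenotype,
)
from .pedigree import Individual, correction_factor, kinship, parse_pedigree

log = logging.getLogger(__name__)

METHODS = ("t2f", "cmcf", "fpcaf", "chimin")

TABLE_COLUMNS = ["gene", "chrom", "n_variants", "p_corr"] + [
    f"{m}_{suffix}" for m in METHODS for suffix in ("stat", "df", "p")
]

DEFAULT_ALPHA_GRID = (0.05, 0.01, 0.001, 0.0001)


@dataclass
class ScanConfig:
    """Tunable thresholds of the genome scan."""

    rare_maf: float = 0.01           # CMC collapsing threshold
    fpca_var: float = 0.85           # cumulative variance fraction kept by FPCA
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    family_alpha: float = 0.05       # family-wise level for Bonferroni
    bonferroni: bool = True          # append the Bonferroni level to the grid
    bonferroni_denominator: str = "loaded"  # "loaded" | "analyzed"


@dataclass
class ScanResult:
    """Per-gene test table plus the significance-level grid."""

    table: pd.DataFrame
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    n_genes_loaded: int = 0
    family_alpha: float = 0.05

    @property
    def bonferroni(self) -> float:
        return bonferroni_threshold(max(self.n_genes_loaded, 1), self.family_alpha)

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(self.alpha_grid) + (self.bonferroni,)


def bonferroni_threshold(n_genes: int, family_alpha: float = 0.05) -> float:
    """Per-gene significance level controlling the family-wise error rate."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 < family_alpha < 1.0:
        raise ValueError("family_alpha must lie in (0, 1)")
    return family_alpha / n_genes


def scan_regions(
    region_matrices: Sequence[tuple[GeneRegion, GenotypeMatrix]],
    cases: Sequence[str],
    controls: Sequence[str],
    pcorr,
    config: ScanConfig | None = None,
) -> ScanResult:
    """Run all applicable tests on pre-extracted per-gene matrices.

    Genes with zero polymorphic variants produce an all-NA row (reason
    logged); genes with fewer than 3 variants get NA in the FPCA columns
    only. Output row order follows the input region order.
    """
    config = config or ScanConfig()
    rows = []
    pc_value = float(getattr(pcorr, "value", pcorr))
    for region, matrix in region_matrices:
        row = {c: np.nan for c in TABLE_COLUMNS}
        row.update(gene=region.name, chrom=region.chrom,
                   n_variants=matrix.n_variants, p_corr=pc_value)
        if matrix.n_variants == 0:
            log.info("gene %s skipped: no polymorphic variants", region.name)
        else:
            fit = GeneAssociation(matrix, cases, controls, pcorr).fit(
                methods=METHODS,
                rare_threshold=config.rare_maf,
                variance_explained=config.fpca_var,
            )
            for method, result in fit.results.items():
                row[f"{method}_stat"] = result.statistic
                row[f"{method}_df"] = result.df
                row[f"{method}_p"] = result.p_value
            for method, reason in fit.skipped.items():
                log.info("gene %s: %s skipped (%s)", region.name, method, reason)
        rows.append(row)
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return ScanResult(
        table=table,
        alpha_grid=tuple(config.alpha_grid),
        n_genes_loaded=len(region_matrices),
        family_alpha=config.family_alpha,
    )


def scan_genome(
    vcf: str | Path,
    regions: Sequence[GeneRegion] | str | Path,
    pedigree: Sequence[Individual] | str | Path,
    phenotype: pd.DataFrame | str | Path,
    config: ScanConfig | None = None,
) -> ScanResult:
    """Full scan from files: VCF + BED regions + PED/FAM + phenotype TSV.

    The kinship matrix is computed over the *whole* pedigree (ancestors
    contribute to kinship even when unphenotyped); the correction factor is
    then computed once for the analyzed case/control partition and shared by
    every gene.
    """
    from .genotypes import load_regions

    config = config or ScanConfig()
    if not isinstance(pedigree, (list, tuple)):
        pedigree = parse_pedigree(pedigree)
    if isinstance(regions, (str, Path)):
        regions = load_regions(regions)
    if isinstance(phenotype, (str, Path)):
        phenotype = read_phenotype(phenotype)

    ped_ids = {ind.individual_id for ind in pedigree}
    cases, controls = phenotype_partition(phenotype)
    cases = [i for i in cases if i in ped_ids]
    controls = [i for i in controls if i in ped_ids]
    analyzed = cases + controls
    if not analyzed:
        raise ValueError("no phenotyped individuals overlap the pedigree")

    matrices = extract_all_regions(vcf, regions, analyzed)
    phi = kinship(pedigree)
    pcorr = correction_factor(phi, cases, controls)
    return scan_regions(
        [(r, matrices[r.name]) for r in regions], cases, controls, pcorr, config
    )


def count_significant(result: ScanResult, method: str, alpha: float) -> int:
    """Number of analyzed genes with p <= alpha for a method."""
    p = result.table[f"{method}_p"]
    return int((p <= alpha).sum())


def significant_genes(result: ScanResult, method: str, alpha: float) -> set[str]:
    p = result.table[f"{method}_p"]
    return set(result.table.loc[p <= alpha, "gene"])


def significance_table(result: ScanResult, methods: Sequence[str] = METHODS) -> pd.DataFrame:
    """Counts of significant genes per method at each grid level (Bonferroni
    level appended when configured) — the structure of a per-level summary."""
    data = [
        [count_significant(result, m, level) for level in result.levels]
        for m in methods
    ]
    return pd.DataFrame(
        data,
        index=[m.upper() for m in methods],
        columns=[f"{level:.3g}" for level in result.levels],
    )


@dataclass
class OverlapCounts:
    """Venn-style exclusive-region counts for significant gene sets."""

    methods: tuple[str, ...]
    regions: dict[tuple[str, ...], int]
    external: dict[str, int] | None = None


def overlap_sets(
    result: ScanResult,
    methods: Sequence[str],
    alpha: float,
    external_list: Iterable[str] | None = None,
) -> OverlapCounts:
    """All-subset exclusive intersection counts of significant gene sets.

    ``regions`` maps each non-empty subset of methods (sorted tuple) to the
    number of genes significant for exactly that subset. When an external
    gene list is supplied, ``external`` gives each method's intersection
    count with it.
    """
    sets = {m: significant_genes(result, m, alpha) for m in methods}
    universe = set().union(*sets.values()) if sets else set()
    regions: dict[tuple[str, ...], int] = {}
    from itertools import combinations

    for r in range(1, len(methods) + 1):
        for subset in combinations(sorted(methods), r):
            inside = set(universe)
            for m in subset:
                inside &= sets[m]
            for m in methods:
                if m not in subset:
                    inside -= sets[m]
            regions[subset] = len(inside)
    external = None
    if external_list is not None:
        ext = set(external_list)
        external = {m: len(sets[m] & ext) for m in methods}
    return OverlapCounts(methods=tuple(sorted(methods)), regions=regions, external=external)


def write_scan(result: ScanResult, path: str | Path) -> None:
    """Write the per-gene table as deterministic TSV (NA for skips)."""
    table = result.table.copy()
    for m in METHODS:
        col = f"{m}_df"
        table[col] = table[col].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    table["n_variants"] = table["n_variants"].astype(int)
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_scan(path: str | Path) -> pd.DataFrame:
    """Read a scan table written by :func:`write_scan`."""
    return pd.read_csv(path, sep="\t", na_values="NA", dtype={"gene": str, "chrom": str})
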