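"""Synthetic pedigree-sequence simulator: gene dropping and a liability trait.

Emulates the statistical structure the association tests assume: replicated
template pedigrees (trio / nuclear / three-generation), founder genotypes
drawn per variant from a mixed common/rare site-frequency spectrum in
linkage equilibrium, Mendelian transmission to descendants (one allele per
parent per variant, fair transmission coin), and a binary phenotype from a
logistic liability model with configurable causal genes. Replicates share
the pedigree structure and gene map and redraw founders, transmissions and
phenotypes, so replicates are i.i.d. datasets as the evaluator assumes.

Everything is deterministic under the configured seed; per-replicate
substreams are derived from fixed offsets of the base seed.
"""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .genotypes import GeneRegion, GenotypeMatrix, finalize_matrix, write_vcf
from .pedigree import Individual, topological_order

GENE_SPACING = 100_000   # bp between consecutive simulated gene starts
GENE_LENGTH = 50_000     # bp spanned by each simulated gene


@dataclass
class SimulationConfig:
    """Study conditions of a simulated family-sequencing experiment.

    Defaults describe the null calibration study: 300 nuclear families of
    four (1,200 individuals), 1,000 genes of 5-20 variants each with an
    even mixture of rare (MAF ~ U(0.001, 0.01)) and common
    (MAF ~ U(0.05, 0.5)) variants, no causal gene, and a binary trait of
    25% prevalence drawn independently of genotype. Causal scenarios place
    per-variant log-odds effects on a chosen number of rare (carrier
    indicator, ``beta_rare``) and common (additive dosage, ``beta_common``)
    variants inside each causal gene.
    """

    n_pedigrees: int = 300
    pedigree_template: str = "nuclear"   # "trio" | "nuclear" | "three_generation"
    n_children: int = 2                  # children per mating (nuclear template)
    n_genes: int = 1000
    variants_per_gene: tuple[int, int] = (5, 20)   # inclusive range
    rare_fraction: float = 0.5
    rare_maf_range: tuple[float, float] = (0.001, 0.01)
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_genes: int = 0
    n_causal_rare: int = 3               # causal rare variants per causal gene
    n_causal_common: int = 0             # causal common variants per causal gene
    beta_rare: float = 1.5               # log-odds per rare-carrier indicator
    beta_common: float = 0.25            # log-odds per minor-allele copy
    prevalence: float = 0.25
    n_replicates: int = 1
    seed: int = 0
    chrom: str = "3"

    def __post_init__(self) -> None:
        lo, hi = self.variants_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("variants_per_gene must be an increasing range >= 1")
        if not 0.0 <= self.rare_fraction <= 1.0:
            raise ValueError("rare_fraction must lie in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_causal_genes > self.n_genes:
            raise ValueError("n_causal_genes cannot exceed n_genes")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variants_per_gene"] = list(self.variants_per_gene)
        d["rare_maf_range"] = list(self.rare_maf_range)
        d["common_maf_range"] = list(self.common_maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("variants_per_gene", "rare_maf_range", "common_maf_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def sha256(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class GeneSpec:
    """Fixed per-gene map: positions, allele frequencies, causal assignment."""

    name: str
    chrom: str
    start: int                 # BED 0-based
    end: int
    positions: np.ndarray      # 1-based, sorted, inside (start, end]
    mafs: np.ndarray
    is_rare: np.ndarray        # bool per variant
    causal_common: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    causal_rare: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def region(self) -> GeneRegion:
        return GeneRegion(name=self.name, chrom=self.chrom, start=self.start, end=self.end)

    @property
    def is_causal(self) -> bool:
        return self.causal_common.size + self.causal_rare.size > 0


@dataclass
class SimulatedReplicate:
    """One in-memory replicate dataset: everything a scan needs."""

    individuals: list[Individual]
    genes: list[GeneSpec]
    matrices: dict[str, GenotypeMatrix]      # finalized, analysis-ready
    phenotype: pd.DataFrame                  # columns fid, iid, pheno (2/1)
    causal_genes: list[str]
    replicate: int


def simulate_pedigrees(config: SimulationConfig) -> list[Individual]:
    """Replicate the template pedigree ``n_pedigrees`` times with unique ids.

    Templates: ``trio`` (father, mother, child), ``nuclear`` (parents plus
    ``n_children``), ``three_generation`` (two grandparental couples, their
    two children married to each other, two grandchildren).
    """
    individuals: list[Individual] = []
    for fam in range(1, config.n_pedigrees + 1):
        fid = f"F{fam:04d}"

        def iid(k: int) -> str:
            return f"{fid}_{k}"

        def add(k, fa, mo, sex):
            individuals.append(
                Individual(
                    individual_id=iid(k),
                    family_id=fid,
                    father_id=None if fa is None else iid(fa),
                    mother_id=None if mo is None else iid(mo),
                    sex=sex,
                )
            )

        if config.pedigree_template == "trio":
            add(1, None, None, "male")
            add(2, None, None, "female")
            add(3, 1, 2, "male")
        elif config.pedigree_template == "nuclear":
            add(1, None, None, "male")
            add(2, None, None, "female")
            for c in range(config.n_children):
                add(3 + c, 1, 2, "male" if c % 2 == 0 else "female")
        elif config.pedigree_template == "three_generation":
            add(1, None, None, "male")
            add(2, None, None, "female")
            add(3, None, None, "male")
            add(4, None, None, "female")
            add(5, 1, 2, "male")
            add(6, 3, 4, "female")
            add(7, 5, 6, "male")
            add(8, 5, 6, "female")
        else:
            raise ValueError(f"unknown pedigree template {config.pedigree_template!r}")
    return individuals


def make_gene_map(config: SimulationConfig) -> list[GeneSpec]:
    """Fixed gene map shared by all replicates (depends only on the seed).

    Genes are laid out on one chromosome at regular spacing; variant counts,
    positions, the rare/common split and per-variant MAFs are drawn once.
    Causal genes and their causal variants are chosen here so that causal
    labels are identical across replicates.
    """
    rng = np.random.default_rng([config.seed, 101])
    lo, hi = config.variants_per_gene
    causal_idx = set(
        rng.choice(config.n_genes, size=config.n_causal_genes, replace=False).tolist()
        if config.n_causal_genes
        else []
    )
    genes: list[GeneSpec] = []
    for g in range(config.n_genes):
        m = int(rng.integers(lo, hi + 1))
        start = g * GENE_SPACING
        positions = np.sort(
            rng.choice(np.arange(start + 1, start + GENE_LENGTH + 1), size=m, replace=False)
        )
        is_rare = rng.random(m) < config.rare_fraction
        mafs = np.where(
            is_rare,
            rng.uniform(*config.rare_maf_range, size=m),
            rng.uniform(*config.common_maf_range, size=m),
        )
        causal_common = np.array([], dtype=int)
        causal_rare = np.array([], dtype=int)
        if g in causal_idx:
            rare_pool = np.flatnonzero(is_rare)
            common_pool = np.flatnonzero(~is_rare)
            causal_rare = np.sort(
                rng.choice(rare_pool, size=min(config.n_causal_rare, rare_pool.size),
                           replace=False)
            )
            causal_common = np.sort(
                rng.choice(common_pool, size=min(config.n_causal_common, common_pool.size),
                           replace=False)
            )
        genes.append(
            GeneSpec(
                name=f"GENE{g + 1:04d}",
                chrom=config.chrom,
                start=start,
                end=start + GENE_LENGTH,
                positions=positions,
                mafs=mafs,
                is_rare=is_rare,
                causal_common=causal_common,
                causal_rare=causal_rare,
            )
        )
    return genes


def _pedigree_layout(individuals: Sequence[Individual]):
    """Founder rows and generation layers (child, father, mother row indices)."""
    index = {ind.individual_id: i for i, ind in enumerate(individuals)}
    depth = np.zeros(len(individuals), dtype=int)
    for i in topological_order(individuals):
        ind = individuals[i]
        if not ind.is_founder:
            depth[i] = max(depth[index[ind.father_id]], depth[index[ind.mother_id]]) + 1
    founders = np.flatnonzero(depth == 0)
    layers = []
    for d in range(1, int(depth.max()) + 1 if len(depth) else 1):
        rows = np.flatnonzero(depth == d)
        if rows.size == 0:
            continue
        fa = np.array([index[individuals[r].father_id] for r in rows])
        mo = np.array([index[individuals[r].mother_id] for r in rows])
        layers.append((rows, fa, mo))
    return founders, layers


def gene_drop_raw(
    individuals: Sequence[Individual],
    gene: GeneSpec,
    rng: np.random.Generator,
    layout=None,
) -> np.ndarray:
    """Raw simulated-allele dosage matrix (individuals x variants).

    Founder genotypes are Binomial(2, MAF) independently per variant
    (linkage equilibrium among founders); each non-founder receives one
    allele per parent per variant. Given a parent's dosage g, the
    transmitted allele is the simulated allele with probability g/2 — the
    exact Mendelian transmission law for unordered genotypes — and
    transmissions to different children are independent meioses.
    """
    founders, layers = layout if layout is not None else _pedigree_layout(individuals)
    n, m = len(individuals), len(gene.positions)
    dosage = np.zeros((n, m))
    dosage[founders] = rng.binomial(2, gene.mafs, size=(founders.size, m))
    for rows, fa, mo in layers:
        dosage[rows] = rng.binomial(1, dosage[fa] / 2.0) + rng.binomial(1, dosage[mo] / 2.0)
    return dosage


def gene_drop(
    individuals: Sequence[Individual],
    gene: GeneSpec,
    rng: np.random.Generator,
    layout=None,
) -> GenotypeMatrix:
    """Gene-drop and return an analysis-ready (oriented, filtered) matrix."""
    raw = gene_drop_raw(individuals, gene, rng, layout)
    ids = [ind.individual_id for ind in individuals]
    raw_variants = [
        (gene.chrom, int(p), "A", "T") for p in gene.positions
    ]
    return finalize_matrix(ids, raw_variants, raw)


def simulate_phenotype(
    individuals: Sequence[Individual],
    genes: Sequence[GeneSpec],
    raw_matrices: dict[str, np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary phenotype from the logistic liability model.

    P(case) = expit(logit(prevalence) + sum over causal common variants of
    beta_common * dosage + sum over causal rare variants of beta_rare *
    carrier indicator). Disease status is an independent Bernoulli draw per
    individual given genotype (no shared-environment term, so the null with
    no causal gene is exactly exchangeable).
    """
    eta = np.full(len(individuals), logit(config.prevalence))
    for gene in genes:
        if not gene.is_causal:
            continue
        raw = raw_matrices[gene.name]
        for v in gene.causal_common:
            eta = eta + config.beta_common * raw[:, v]
        for v in gene.causal_rare:
            eta = eta + config.beta_rare * (raw[:, v] > 0)
    return rng.binomial(1, expit(eta))


def simulate_dataset(config: SimulationConfig, replicate: int = 0) -> SimulatedReplicate:
    """One complete in-memory replicate (genotypes, phenotype, causal labels)."""
    individuals = simulate_pedigrees(config)
    genes = make_gene_map(config)
    layout = _pedigree_layout(individuals)
    rng = np.random.default_rng([config.seed, 1000 + replicate])
    ids = [ind.individual_id for ind in individuals]

    raw_matrices: dict[str, np.ndarray] = {}
    matrices: dict[str, GenotypeMatrix] = {}
    for gene in genes:
        raw = gene_drop_raw(individuals, gene, rng, layout)
        raw_matrices[gene.name] = raw
        raw_variants = [(gene.chrom, int(p), "A", "T") for p in gene.positions]
        matrices[gene.name] = finalize_matrix(ids, raw_variants, raw)

    y = simulate_phenotype(individuals, genes, raw_matrices, config, rng)
    phenotype = pd.DataFrame(
        {
            "fid": [ind.family_id for ind in individuals],
            "iid": ids,
            "pheno": (y + 1).astype(int),  # 2 = case, 1 = control
        }
    )
    return SimulatedReplicate(
        individuals=individuals,
        genes=genes,
        matrices=matrices,
        phenotype=phenotype,
        causal_genes=[g.name for g in genes if g.is_causal],
        replicate=replicate,
    )


_SEX_CODE = {"male": "1", "female": "2", "unknown": "0"}


def write_fam(individuals: Sequence[Individual], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind in individuals:
            fh.write(
                "\t".join(
                    [
                        ind.family_id,
                        ind.individual_id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_CODE[ind.sex],
                        {"case": "2", "control": "1"}.get(ind.affection, "0"),
                    ]
                )
                + "\n"
            )


def write_bed(genes: Sequence[GeneSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\n")


def generate_replicates(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write ``n_replicates`` datasets to disk and return the manifest.

    Layout: shared ``pedigree.fam``, ``genes.bed`` and ``causal_genes.txt``;
    per replicate ``rep###.vcf`` and ``rep###_pheno.tsv``; a
    ``manifest.yaml`` recording the seed and a hash of the configuration.
    Reruns with the same configuration are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "n_replicates": config.n_replicates,
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "files": {},
    }
    first = simulate_dataset(config, 0)
    write_fam(first.individuals, outdir / "pedigree.fam")
    write_bed(first.genes, outdir / "genes.bed")
    with open(outdir / "causal_genes.txt", "w") as fh:
        for name in first.causal_genes:
            fh.write(name + "\n")
    manifest["files"]["pedigree"] = "pedigree.fam"
    manifest["files"]["regions"] = "genes.bed"
    manifest["files"]["causal_genes"] = "causal_genes.txt"
    manifest["files"]["replicates"] = []

    ids = [ind.individual_id for ind in first.individuals]
    for r in range(config.n_replicates):
        ds = first if r == 0 else simulate_dataset(config, r)
        vcf_name = f"rep{r + 1:03d}.vcf"
        pheno_name = f"rep{r + 1:03d}_pheno.tsv"
        write_vcf(outdir / vcf_name, ids, [ds.matrices[g.name] for g in ds.genes])
        ds.phenotype.to_csv(outdir / pheno_name, sep="\t", index=False)
        manifest["files"]["replicates"].append({"vcf": vcf_name, "phenotype": pheno_name})

    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
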