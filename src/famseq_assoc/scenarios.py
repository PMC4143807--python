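"""Canonical simulation studies: null calibration and the causal power scenario.

These functions wire simulate -> scan -> evaluate in memory, sharing the
kinship matrix across replicates (pedigree structure is fixed; only
genotypes and phenotypes are redrawn), and return a
:class:`~famseq_assoc.evaluate.ReplicateSet` ready for the estimators.
"""
from __future__ import annotations

from .evaluate import ReplicateSet
from .pedigree import correction_factor, kinship
from .scan import ScanConfig, scan_regions
from .simulate import SimulationConfig, simulate_dataset, simulate_pedigrees


def null_calibration_config(seed: int) -> SimulationConfig:
    """Null study: the SimulationConfig defaults (300 nuclear families,
    1,000 genes of 5-20 variants, mixed spectrum, no causal gene)."""
    return SimulationConfig(seed=seed)


def power_scenario_config(seed: int, n_replicates: int = 200) -> SimulationConfig:
    """Causal study: 2 causal genes among 6, each with 3 causal rare
    variants (log-odds 1.5 on the carrier scale) collapsed together with
    null rare background — the regime where per-variant tests retain
    concentrated signal that collapsing dilutes."""
    return SimulationConfig(
        n_genes=6,
        n_causal_genes=2,
        n_replicates=n_replicates,
        seed=seed,
    )


def run_study(
    sim_config: SimulationConfig, scan_config: ScanConfig | None = None
) -> ReplicateSet:
    """Simulate every replicate, scan it, and assemble the ReplicateSet."""
    scan_config = scan_config or ScanConfig()
    individuals = simulate_pedigrees(sim_config)
    phi = kinship(individuals)
    tables = []
    causal: set[str] = set()
    all_genes: set[str] = set()
    for r in range(sim_config.n_replicates):
        ds = simulate_dataset(sim_config, r)
        cases = ds.phenotype.loc[ds.phenotype["pheno"] == 2, "iid"].tolist()
        controls = ds.phenotype.loc[ds.phenotype["pheno"] == 1, "iid"].tolist()
        pcorr = correction_factor(phi, cases, controls)
        result = scan_regions(
            [(g.region, ds.matrices[g.name]) for g in ds.genes],
            cases,
            controls,
            pcorr,
            scan_config,
        )
        tables.append(result.table)
        causal = set(ds.causal_genes)
        all_genes = {g.name for g in ds.genes}
    return ReplicateSet(
        replicates=tables,
        causal_genes=frozenset(causal),
        null_genes=frozenset(all_genes - causal),
    )
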