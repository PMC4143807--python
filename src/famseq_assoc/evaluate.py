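"""Type I error and power estimation from many simulation replicates.

Each replicate is one scan table (per-gene, per-method p-values). Genes are
labeled causal or null; the estimators pool (gene x replicate) pairs as
Bernoulli trials, so the type I error at level alpha is the proportion of
null pairs with p <= alpha and power is the same proportion over causal
pairs. Genes a method skipped (NA p-value, e.g. FPCA on <3 variants) are
excluded from both numerator and denominator, so denominators may differ
across methods.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import pandas as pd

from .scan import METHODS


class RateEstimate(NamedTuple):
    """A detection-rate estimate with its binomial standard error."""

    estimate: float
    se: float
    n_pairs: int


@dataclass
class ReplicateSet:
    """Scan tables of all replicates plus the causal/null gene labels."""

    replicates: list[pd.DataFrame]
    causal_genes: frozenset[str]
    null_genes: frozenset[str]

    def __post_init__(self) -> None:
        self.causal_genes = frozenset(self.causal_genes)
        self.null_genes = frozenset(self.null_genes)
        if self.causal_genes & self.null_genes:
            raise ValueError("causal and null gene sets must be disjoint")
        if not self.replicates:
            raise ValueError("need at least one replicate")
        labeled = self.causal_genes | self.null_genes
        for k, table in enumerate(self.replicates):
            present = set(table["gene"])
            missing = labeled - present
            if missing:
                raise ValueError(
                    f"replicate {k} lacks labeled genes: {sorted(missing)[:5]}"
                )


def _detection_rate(
    reps: ReplicateSet,
    genes: frozenset[str],
    method: str,
    alpha: float,
    per_replicate: bool,
) -> RateEstimate:
    if not genes:
        raise ValueError("gene set is empty")
    col = f"{method}_p"
    hits, total = 0, 0
    fractions = []
    for table in reps.replicates:
        p = table.loc[table["gene"].isin(genes), col].dropna()
        if len(p):
            h = int((p <= alpha).sum())
            hits += h
            total += len(p)
            fractions.append(h / len(p))
    if total == 0:
        raise ValueError(f"no analyzable (gene x replicate) pairs for {method}")
    if per_replicate:
        est = sum(fractions) / len(fractions)
        if len(fractions) > 1:
            var = sum((f - est) ** 2 for f in fractions) / (len(fractions) - 1)
            se = math.sqrt(var / len(fractions))
        else:
            se = float("nan")
        return RateEstimate(est, se, total)
    est = hits / total
    return RateEstimate(est, math.sqrt(est * (1.0 - est) / total), total)


def type1_error(
    reps: ReplicateSet, method: str, alpha: float, per_replicate: bool = False
) -> RateEstimate:
    """Proportion of null (gene x replicate) pairs significant at alpha."""
    return _detection_rate(reps, reps.null_genes, method, alpha, per_replicate)


def power(
    reps: ReplicateSet, method: str, alpha: float, per_replicate: bool = False
) -> RateEstimate:
    """Proportion of causal (gene x replicate) pairs significant at alpha."""
    return _detection_rate(reps, reps.causal_genes, method, alpha, per_replicate)


def evaluation_table(
    reps: ReplicateSet,
    kind: str = "type1",
    alphas: Sequence[float] = (0.05, 0.01, 0.001, 0.0001),
    methods: Sequence[str] = METHODS,
) -> pd.DataFrame:
    """Rows = alpha levels, columns = methods — the layout of a type-I-error
    or power summary table. ``kind`` is "type1" or "power"."""
    estimator = {"type1": type1_error, "power": power}[kind]
    data = {
        m.upper(): [estimator(reps, m, a).estimate for a in alphas] for m in methods
    }
    return pd.DataFrame(data, index=[f"{a:g}" for a in alphas])
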