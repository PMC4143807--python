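"""Pedigree parsing, exact kinship coefficients, and the familial correction factor.

Case-control statistics derived for unrelated samples understate the sampling
variance of an allele-frequency contrast when the sample contains relatives:
dosages of individuals *i* and *j* are correlated with coefficient 2φ_ij,
where φ_ij is the kinship coefficient (the probability that two alleles drawn
one from each individual are identical by descent). The correction factor
computed here, ``P_corr``, is the ratio of the pedigree-aware variance of the
case/control mean-dosage difference to its value under independence; dividing
a population-based chi-square statistic by it restores the nominal null
distribution for pedigree samples.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MISSING_PARENT = "0"

log = logging.getLogger(__name__)


class PedigreeError(ValueError):
    """Structural problem in a pedigree: cycles, half-specified parents,
    duplicate ids, or parent ids that resolve to no individual."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    Parents are either both known or both ``None`` (a founder). Affection is
    the dichotomous phenotype decoded from PED column 6.
    """

    individual_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: str = "unknown"        # "male" | "female" | "unknown"
    affection: str = "missing"  # "case" | "control" | "missing"

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.individual_id!r}: one parent recorded and one "
                "missing; parents must be both present or both absent"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


_SEX = {"1": "male", "2": "female"}
_AFFECTION = {"2": "case", "1": "control"}


def parse_pedigree(path: str | Path, missing_parent: str = MISSING_PARENT) -> list[Individual]:
    """Parse a PLINK-dialect PED/FAM file into a list of :class:`Individual`.

    Columns (whitespace-separated): family id, individual id, father id,
    mother id, sex (1=male, 2=female, other=unknown), phenotype
    (2=case, 1=control, 0/-9=missing). Extra columns are ignored.

    Raises :class:`PedigreeError` on duplicate ids, half-specified parents,
    parent ids absent from the same family, or cycles in the parent links.
    """
    individuals: list[Individual] = []
    seen: set[tuple[str, str]] = set()
    iids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 6:
                raise PedigreeError(f"{path}, line {lineno}: expected >=6 columns, got {len(fields)}")
            fid, iid, fa, mo, sex, phe = fields[:6]
            key = (fid, iid)
            if key in seen:
                raise PedigreeError(f"duplicate individual ({fid}, {iid})")
            if iid in iids:
                raise PedigreeError(
                    f"individual id {iid!r} reused across families; ids must be unique"
                )
            seen.add(key)
            iids.add(iid)
            individuals.append(
                Individual(
                    individual_id=iid,
                    family_id=fid,
                    father_id=None if fa == missing_parent else fa,
                    mother_id=None if mo == missing_parent else mo,
                    sex=_SEX.get(sex, "unknown"),
                    affection=_AFFECTION.get(phe, "missing"),
                )
            )
    _validate_structure(individuals)
    return individuals


def _validate_structure(individuals: Sequence[Individual]) -> None:
    by_family: dict[str, set[str]] = {}
    for ind in individuals:
        by_family.setdefault(ind.family_id, set()).add(ind.individual_id)
    for ind in individuals:
        for parent in (ind.father_id, ind.mother_id):
            if parent is not None and parent not in by_family[ind.family_id]:
                raise PedigreeError(
                    f"individual {ind.individual_id!r}: parent {parent!r} not found "
                    f"in family {ind.family_id!r}"
                )
    topological_order(individuals)  # raises on cycles


def topological_order(individuals: Sequence[Individual]) -> list[int]:
    """Indices of ``individuals`` ordered parents-before-children.

    Raises :class:`PedigreeError` naming an individual on a cycle (an
    individual that is its own ancestor).
    """
    index = {ind.individual_id: i for i, ind in enumerate(individuals)}
    children: dict[int, list[int]] = {i: [] for i in range(len(individuals))}
    n_parents = np.zeros(len(individuals), dtype=int)
    for i, ind in enumerate(individuals):
        for parent in (ind.father_id, ind.mother_id):
            if parent is not None:
                children[index[parent]].append(i)
                n_parents[i] += 1
    order: list[int] = []
    ready = [i for i in range(len(individuals)) if n_parents[i] == 0]
    while ready:
        i = ready.pop()
        order.append(i)
        for c in children[i]:
            n_parents[c] -= 1
            if n_parents[c] == 0:
                ready.append(c)
    if len(order) < len(individuals):
        stuck = next(ind for i, ind in enumerate(individuals) if n_parents[i] > 0)
        raise PedigreeError(
            f"cycle in parent links involving individual {stuck.individual_id!r}"
        )
    return order


@dataclass
class KinshipMatrix:
    """Pairwise kinship coefficients φ for a set of individuals.

    ``phi`` is symmetric with φ_ii = (1 + f_i)/2 (f_i the inbreeding
    coefficient) and zero between members of different families.
    """

    ids: list[str]
    phi: np.ndarray

    def __post_init__(self) -> None:
        self._index = {iid: i for i, iid in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise PedigreeError("duplicate ids in kinship matrix")

    def indices(self, ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._index[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not present in kinship matrix") from None

    def coefficient(self, a: str, b: str) -> float:
        return float(self.phi[self._index[a], self._index[b]])


def kinship(individuals: Sequence[Individual]) -> KinshipMatrix:
    """Exact recursive kinship matrix of a pedigree.

    Founders are mutually unrelated and non-inbred (φ = 1/2 on the diagonal,
    0 off it). For a non-founder *j* with parents *p* and *m* and any earlier
    individual *i* that is not a descendant of *j*:
    φ_ij = (φ_ip + φ_im)/2, and φ_jj = (1 + φ_pm)/2. Individuals may appear
    in any order; the recursion runs over a topological sort.
    """
    n = len(individuals)
    ids = [ind.individual_id for ind in individuals]
    index = {iid: i for i, iid in enumerate(ids)}
    if len(index) != n:
        raise PedigreeError("individual ids must be unique for kinship computation")
    phi = np.zeros((n, n))
    done = np.zeros(n, dtype=bool)
    for j in topological_order(individuals):
        ind = individuals[j]
        prev = np.flatnonzero(done)
        if ind.is_founder:
            phi[j, j] = 0.5
        else:
            fa, mo = index[ind.father_id], index[ind.mother_id]
            phi[j, prev] = 0.5 * (phi[fa, prev] + phi[mo, prev])
            phi[prev, j] = phi[j, prev]
            phi[j, j] = 0.5 * (1.0 + phi[fa, mo])
        done[j] = True
    return KinshipMatrix(ids=ids, phi=phi)


@dataclass(frozen=True)
class CorrectionFactor:
    """Familial variance-inflation factor for a case/control partition.

    ``value`` multiplies the independence variance of the case-control
    mean-dosage difference to give its variance under the pedigree
    correlation; equals 1 exactly for mutually unrelated, non-inbred samples.
    """

    value: float
    n_cases: int
    n_controls: int


def correction_factor(
    phi: KinshipMatrix, cases: Iterable[str], controls: Iterable[str]
) -> CorrectionFactor:
    """Compute P_corr, the kinship correction factor, for a partition.

    With A the case set and Ā the control set, dosage covariances scale as
    Cov(g_i, g_j) = 2φ_ij σ², so

        Var(x̄_A − x̄_Ā) / σ² =
            ΣΣ_{A} 2φ_ij / n_A² + ΣΣ_{Ā} 2φ_ij / n_Ā²
            − 2 ΣΣ_{A×Ā} 2φ_ij / (n_A n_Ā)

    and P_corr is that quantity divided by the independence value
    1/n_A + 1/n_Ā (diagonal terms contribute 2φ_ii = 1 + f_i). The cross
    term vanishes when no case is related to any control.
    """
    case_ids = list(cases)
    control_ids = list(controls)
    if not case_ids or not control_ids:
        raise ValueError("case and control sets must both be non-empty")
    overlap = set(case_ids) & set(control_ids)
    if overlap:
        raise ValueError(f"case and control sets overlap: {sorted(overlap)[:5]}")
    ia = phi.indices(case_ids)
    iu = phi.indices(control_ids)
    two_phi = 2.0 * phi.phi
    na, nu = len(ia), len(iu)
    within = two_phi[np.ix_(ia, ia)].sum() / na**2 + two_phi[np.ix_(iu, iu)].sum() / nu**2
    cross = 2.0 * two_phi[np.ix_(ia, iu)].sum() / (na * nu)
    value = (within - cross) / (1.0 / na + 1.0 / nu)
    if value <= 1e-12:
        raise ValueError(
            "degenerate case/control partition: variance of the group contrast "
            "is numerically zero under the pedigree correlation"
        )
    return CorrectionFactor(value=float(value), n_cases=na, n_controls=nu)


def case_control_partition(individuals: Sequence[Individual]) -> tuple[list[str], list[str]]:
    """Split pedigree members by affection status; missing are excluded."""
    cases = [i.individual_id for i in individuals if i.affection == "case"]
    controls = [i.individual_id for i in individuals if i.affection == "control"]
    return cases, controls
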