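"""The four pedigree-corrected gene-based association statistics.

Each gene region is tested as one unit with four statistics:

* generalized T^2 — a Hotelling-type contrast of the case and control mean
  dosage vectors against the pooled within-group covariance;
* CMC — rare columns (MAF below a threshold) are collapsed to a single
  carrier indicator before the same T^2 machinery, concentrating dispersed
  rare-variant signal into one degree of freedom;
* FPCA — each individual's dosages across the gene are smoothed into a
  function of (rescaled) genomic position via a B-spline basis; group means
  of the leading functional principal component scores are contrasted;
* chi-square minimum — the smallest p-value over per-variant 2x2 allelic
  chi-square tests, reported raw (deliberately without within-gene
  multiplicity adjustment, which is why it is anti-conservative).

Every statistic is divided by the familial correction factor P_corr so that
its null distribution remains (asymptotically) chi-square when the sample
contains relatives. The statsmodels-style front end is
:class:`GeneAssociation` / :class:`GeneAssociationResults`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

from .genotypes import GenotypeMatrix, Variant, allele_counts
from .pedigree import CorrectionFactor, Individual, correction_factor, kinship

__all__ = [
    "TestResult",
    "GeneSkipped",
    "t2_family",
    "cmc_collapse",
    "cmc_family",
    "fpca_family",
    "chi_min_family",
    "GeneAssociation",
    "GeneAssociationResults",
]

PINV_RTOL = 1e-8  # relative singular-value cutoff for the pooled covariance


class GeneSkipped(Exception):
    """Gene cannot be analyzed by a method (e.g. <3 variants for FPCA)."""


@dataclass(frozen=True)
class TestResult:
    """One method's result for one gene region."""

    method: str            # "T2F" | "CMCF" | "FPCAF" | "CHIMIN"
    statistic: float
    df: int
    p_value: float
    n_variants_used: int
    p_corr_applied: float

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("statistic must be non-negative")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


def _pcorr_value(pcorr: CorrectionFactor | float) -> float:
    value = float(getattr(pcorr, "value", pcorr))
    if value <= 0:
        raise ValueError("correction factor must be positive")
    return value


def _pinv_rank(S: np.ndarray, rtol: float = PINV_RTOL) -> tuple[np.ndarray, int]:
    """Moore-Penrose pseudo-inverse and numerical rank from one SVD."""
    u, s, vt = np.linalg.svd(S, hermitian=True)
    if s.size == 0 or s[0] <= 0:
        return np.zeros_like(S), 0
    keep = s > rtol * s[0]
    inv = (vt[keep].T / s[keep]) @ u[:, keep].T
    return inv, int(keep.sum())


def _group_rows(
    matrix: GenotypeMatrix, cases: Iterable[str], controls: Iterable[str]
) -> tuple[np.ndarray, np.ndarray]:
    rows_a = matrix.rows(cases)
    rows_u = matrix.rows(controls)
    if rows_a.size < 2 or rows_u.size < 2:
        raise ValueError("each of cases and controls needs >=2 individuals "
                         "for covariance estimation")
    return rows_a, rows_u


def _t2_core(X: np.ndarray, rows_a: np.ndarray, rows_u: np.ndarray) -> tuple[float, int]:
    """Uncorrected generalized T^2 and its degrees of freedom (rank of S)."""
    na, nu = rows_a.size, rows_u.size
    n = na + nu
    Xa, Xu = X[rows_a], X[rows_u]
    d = Xa.mean(axis=0) - Xu.mean(axis=0)
    Za = Xa - Xa.mean(axis=0)
    Zu = Xu - Xu.mean(axis=0)
    S = (Za.T @ Za + Zu.T @ Zu) / (n - 2)
    S_pinv, rank = _pinv_rank(np.atleast_2d(S))
    stat = (na * nu / n) * float(d @ S_pinv @ d)
    return max(stat, 0.0), max(rank, 1)


def t2_family(
    matrix: GenotypeMatrix,
    cases: Iterable[str],
    controls: Iterable[str],
    pcorr: CorrectionFactor | float = 1.0,
) -> TestResult:
    """Generalized T^2 for pedigree data: T_F^2 = T^2 / P_corr.

    T^2 = (n_A n_Ā / n) d' S^+ d with d the case-minus-control mean dosage
    vector and S the pooled within-group covariance (pseudo-inverted at
    relative tolerance 1e-8); df is the numerical rank of S and the p-value
    the chi-square upper tail.
    """
    if matrix.n_variants < 1:
        raise GeneSkipped("no polymorphic variants")
    pc = _pcorr_value(pcorr)
    rows_a, rows_u = _group_rows(matrix, cases, controls)
    stat, df = _t2_core(matrix.dosage, rows_a, rows_u)
    stat /= pc
    return TestResult("T2F", stat, df, float(stats.chi2.sf(stat, df)),
                      matrix.n_variants, pc)


def cmc_collapse(matrix: GenotypeMatrix, rare_threshold: float = 0.01) -> GenotypeMatrix:
    """Collapse rare columns (MAF < threshold) into one carrier indicator.

    Common columns pass through unchanged (in their original order, followed
    by the indicator); with no rare column the input is returned as-is.
    """
    if not 0.0 < rare_threshold <= 0.5:
        raise ValueError("rare_threshold must lie in (0, 0.5]")
    rare = [j for j, v in enumerate(matrix.variants) if v.maf < rare_threshold]
    if not rare:
        return matrix
    common = [j for j in range(matrix.n_variants) if j not in set(rare)]
    indicator = (matrix.dosage[:, rare] > 0).any(axis=1).astype(float)
    first_rare = matrix.variants[rare[0]]
    pseudo = Variant(
        chrom=first_rare.chrom,
        pos=min(matrix.variants[j].pos for j in rare),
        ref="N",
        alt="<CARRIER>",
        maf=float(min(indicator.mean() / 2.0, 0.5)),
        minor_is_alt=True,
    )
    dosage = (
        np.column_stack([matrix.dosage[:, common], indicator])
        if common
        else indicator[:, None]
    )
    variants = [matrix.variants[j] for j in common] + [pseudo]
    return GenotypeMatrix(ids=list(matrix.ids), variants=variants, dosage=dosage)


def cmc_family(
    matrix: GenotypeMatrix,
    cases: Iterable[str],
    controls: Iterable[str],
    pcorr: CorrectionFactor | float = 1.0,
    rare_threshold: float = 0.01,
) -> TestResult:
    """CMC for pedigree data: collapse rare columns, then T^2 / P_corr."""
    if matrix.n_variants < 1:
        raise GeneSkipped("no polymorphic variants")
    pc = _pcorr_value(pcorr)
    reduced = cmc_collapse(matrix, rare_threshold)
    rows_a, rows_u = _group_rows(reduced, cases, controls)
    stat, df = _t2_core(reduced.dosage, rows_a, rows_u)
    stat /= pc
    return TestResult("CMCF", stat, df, float(stats.chi2.sf(stat, df)),
                      matrix.n_variants, pc)


def _bspline_design(x: np.ndarray, n_basis: int, order: int) -> np.ndarray:
    """Design matrix of a clamped uniform B-spline basis on [0, 1]."""
    degree = order - 1
    n_internal = n_basis - order
    knots = np.concatenate([
        np.zeros(order),
        np.arange(1, n_internal + 1) / (n_internal + 1),
        np.ones(order),
    ])
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def fpca_family(
    matrix: GenotypeMatrix,
    cases: Iterable[str],
    controls: Iterable[str],
    pcorr: CorrectionFactor | float = 1.0,
    variance_explained: float = 0.85,
    n_basis_max: int = 10,
    n_grid: int = 101,
) -> TestResult:
    """Functional-PCA score test for pedigree data: T_FPCAF = T_FPCA / P_corr.

    Variant positions are rescaled to [0, 1]; each individual's dosage
    profile is least-squares fitted with a clamped B-spline basis of order
    min(4, n_basis) with n_basis = min(m, 10); principal components of the
    smoothed profiles (evaluated on a uniform grid) are retained up to the
    requested cumulative variance fraction; the statistic contrasts group
    mean scores component-wise, each scaled by the pooled within-group score
    variance, and df equals the number of retained components.

    Genes with fewer than 3 variants are skipped: too few points to estimate
    the functional form of allele counts along the gene.
    """
    m = matrix.n_variants
    if m < 3:
        raise GeneSkipped("fewer than 3 variants")
    if not 0.0 < variance_explained <= 1.0:
        raise ValueError("variance_explained must lie in (0, 1]")
    pc = _pcorr_value(pcorr)
    rows_a, rows_u = _group_rows(matrix, cases, controls)
    na, nu = rows_a.size, rows_u.size
    n = matrix.n_individuals

    pos = np.array([v.pos for v in matrix.variants], dtype=float)
    span = pos.max() - pos.min()
    if span <= 0:
        raise GeneSkipped("all variants at one position")
    t = (pos - pos.min()) / span

    n_basis = min(m, n_basis_max)
    order = min(4, n_basis)
    design = _bspline_design(t, n_basis, order)
    grid = np.linspace(0.0, 1.0, n_grid)
    basis_grid = _bspline_design(grid, n_basis, order)

    coeffs, *_ = np.linalg.lstsq(design, matrix.dosage.T, rcond=None)  # (n_basis, n)
    profiles = (basis_grid @ coeffs).T                                  # (n, n_grid)
    centered = profiles - profiles.mean(axis=0)
    _, singular, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = singular**2 / (n - 1)
    total = eigvals.sum()
    if total <= 1e-12:
        raise GeneSkipped("zero total variance of smoothed profiles")
    n_pos = int((eigvals > 1e-12 * eigvals[0]).sum())
    k = int(np.searchsorted(np.cumsum(eigvals) / total, variance_explained) + 1)
    k = min(k, n_pos)

    scores = centered @ vt[:k].T                                        # (n, k)
    sa, su = scores[rows_a], scores[rows_u]
    lam = (((sa - sa.mean(axis=0)) ** 2).sum(axis=0)
           + ((su - su.mean(axis=0)) ** 2).sum(axis=0)) / (n - 2)
    diff = sa.mean(axis=0) - su.mean(axis=0)
    usable = lam > 1e-12 * max(float(lam.max()), 1e-300)
    stat = (na * nu / n) * float((diff[usable] ** 2 / lam[usable]).sum()) / pc
    df = max(int(usable.sum()), 1)
    return TestResult("FPCAF", max(stat, 0.0), df, float(stats.chi2.sf(stat, df)),
                      m, pc)


def pearson_chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square (no continuity correction) of a 2x2 table
    [[a, b], [c, d]]; zero if any margin is empty."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom <= 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def chi_min_family(
    matrix: GenotypeMatrix,
    cases: Iterable[str],
    controls: Iterable[str],
    pcorr: CorrectionFactor | float = 1.0,
    sidak: bool = False,
) -> TestResult:
    """Minimum of per-variant allelic chi-square p-values, P_corr-corrected.

    Each variant's 2x2 minor/major allele-count table (cases vs controls) is
    tested with a 1-df Pearson chi-square; the statistic is divided by
    P_corr before the p lookup. The reported p-value is the raw minimum over
    variants (the anti-conservativeness of this choice is the point of the
    method as a comparator); ``sidak=True`` applies a within-gene Šidák
    adjustment 1 - (1 - p_min)^m instead.
    """
    m = matrix.n_variants
    if m < 1:
        raise GeneSkipped("no polymorphic variants")
    pc = _pcorr_value(pcorr)
    case_ids = list(cases)
    control_ids = list(controls)
    if not case_ids or not control_ids:
        raise ValueError("case and control sets must both be non-empty")
    best_p, best_stat = np.inf, 0.0
    for j in range(m):
        a_minor, a_major = allele_counts(matrix, j, case_ids)
        u_minor, u_major = allele_counts(matrix, j, control_ids)
        stat = pearson_chi2_2x2(a_minor, a_major, u_minor, u_major) / pc
        p = float(stats.chi2.sf(stat, 1))
        if p < best_p:
            best_p, best_stat = p, stat
    if sidak:
        best_p = 1.0 - (1.0 - best_p) ** m
    return TestResult("CHIMIN", best_stat, 1, best_p, m, pc)


class GeneAssociation:
    """Model object: one gene's genotype matrix plus a case/control partition.

    Parameters
    ----------
    matrix : GenotypeMatrix
        Minor-allele dosages for the gene region.
    cases, controls : iterable of str
        Disjoint individual id sets, both present in the matrix.
    pcorr : CorrectionFactor or float, default 1.0
        Familial correction factor; 1 for unrelated samples. Use
        :meth:`from_pedigree` to derive it from pedigree structure.
    """

    def __init__(
        self,
        matrix: GenotypeMatrix,
        cases: Iterable[str],
        controls: Iterable[str],
        pcorr: CorrectionFactor | float = 1.0,
    ) -> None:
        self.matrix = matrix
        self.cases = list(cases)
        self.controls = list(controls)
        self.pcorr = pcorr

    @classmethod
    def from_pedigree(
        cls,
        matrix: GenotypeMatrix,
        individuals: Sequence[Individual],
        cases: Iterable[str],
        controls: Iterable[str],
    ) -> "GeneAssociation":
        phi = kinship(individuals)
        cases = list(cases)
        controls = list(controls)
        return cls(matrix, cases, controls, correction_factor(phi, cases, controls))

    def fit(
        self,
        methods: Sequence[str] = ("t2f", "cmcf", "fpcaf", "chimin"),
        rare_threshold: float = 0.01,
        variance_explained: float = 0.85,
    ) -> "GeneAssociationResults":
        runners = {
            "t2f": lambda: t2_family(self.matrix, self.cases, self.controls, self.pcorr),
            "cmcf": lambda: cmc_family(self.matrix, self.cases, self.controls,
                                       self.pcorr, rare_threshold),
            "fpcaf": lambda: fpca_family(self.matrix, self.cases, self.controls,
                                         self.pcorr, variance_explained),
            "chimin": lambda: chi_min_family(self.matrix, self.cases, self.controls,
                                             self.pcorr),
        }
        results: dict[str, TestResult] = {}
        skipped: dict[str, str] = {}
        for method in methods:
            try:
                results[method] = runners[method]()
            except GeneSkipped as exc:
                skipped[method] = str(exc)
        return GeneAssociationResults(self, results, skipped)


class GeneAssociationResults:
    """Fitted results for one gene: per-method statistics and p-values."""

    def __init__(
        self,
        model: GeneAssociation,
        results: dict[str, TestResult],
        skipped: dict[str, str],
    ) -> None:
        self.model = model
        self.results = results
        self.skipped = skipped

    @property
    def pvalues(self) -> dict[str, float]:
        return {m: r.p_value for m, r in self.results.items()}

    def summary(self) -> str:
        lines = [
            "Gene-based family association tests",
            "=" * 55,
            f"individuals: {self.model.matrix.n_individuals}  "
            f"(cases {len(self.model.cases)}, controls {len(self.model.controls)})",
            f"variants: {self.model.matrix.n_variants}   "
            f"P_corr: {_pcorr_value(self.model.pcorr):.4f}",
            "-" * 55,
            f"{'method':<8}{'statistic':>12}{'df':>5}{'p-value':>12}",
        ]
        for method in ("t2f", "cmcf", "fpcaf", "chimin"):
            if method in self.results:
                r = self.results[method]
                lines.append(f"{r.method:<8}{r.statistic:>12.4f}{r.df:>5d}{r.p_value:>12.3e}")
            elif method in self.skipped:
                lines.append(f"{method.upper():<8}{'skipped':>12}     ({self.skipped[method]})")
        lines.append("=" * 55)
        return "\n".join(lines)
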