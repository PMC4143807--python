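"""Independent oracles used by the test suite.

Everything here is deliberately written along a different code path from the
package: exact rational arithmetic (sympy / fractions) for the small-fixture
statistics, Wright's path-counting formula for kinship, dense explicit
linear algebra for FPCA, and a vectorized label-permutation reference for
the T^2 p-value.
"""
from __future__ import annotations

from fractions import Fraction
from itertools import combinations, product

import numpy as np
import sympy
from scipy.interpolate import BSpline


# ---------------------------------------------------------------- kinship

def kinship_path_counting(individuals):
    """Pairwise kinship via Wright's path-counting formula.

    phi_ij = sum over common ancestors a and over pairs of ascending paths
    (i -> a, j -> a) sharing no node except a of (1/2)^(l1 + l2 + 1) (1 + f_a),
    with l the edge count of a path and f_a the inbreeding coefficient of the
    ancestor (itself phi of a's parents). Exact rational arithmetic.
    """
    parents = {
        ind.individual_id: (ind.father_id, ind.mother_id) for ind in individuals
    }

    def ancestors(x):
        out = {x}
        fa, mo = parents[x]
        for p in (fa, mo):
            if p is not None:
                out |= ancestors(p)
        return out

    def paths_up(x, a):
        """All ascending node-paths from x to a (inclusive)."""
        if x == a:
            return [[x]]
        out = []
        for p in parents[x]:
            if p is not None and a in ancestors(p):
                out.extend([x] + path for path in paths_up(p, a))
        return out

    def inbreeding(x):
        fa, mo = parents[x]
        if fa is None:
            return Fraction(0)
        return phi_pair(fa, mo)

    def phi_pair(i, j):
        if i == j:
            return (1 + inbreeding(i)) / 2
        total = Fraction(0)
        common = ancestors(i) & ancestors(j)
        for a in common:
            for p, q in product(paths_up(i, a), paths_up(j, a)):
                if set(p) & set(q) == {a}:
                    total += Fraction(1, 2) ** (len(p) + len(q) - 1) * (1 + inbreeding(a))
        return total

    ids = [ind.individual_id for ind in individuals]
    n = len(ids)
    phi = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            phi[i, j] = phi[j, i] = float(phi_pair(ids[i], ids[j]))
    return ids, phi


def enumerate_pedigrees(n_members, sex_patterns=None):
    """Yield every acyclic pedigree on ``n_members`` individuals where each
    member's parents (if any) have smaller indices and opposite sexes."""
    from famseq_assoc.pedigree import Individual

    if sex_patterns is None:
        sex_patterns = list(product(["male", "female"], repeat=n_members))
    for sexes in sex_patterns:
        males = [[] for _ in range(n_members)]
        females = [[] for _ in range(n_members)]
        for k in range(1, n_members):
            males[k] = [i for i in range(k) if sexes[i] == "male"]
            females[k] = [i for i in range(k) if sexes[i] == "female"]
        options = []
        for k in range(n_members):
            opts = [None]
            if k > 0:
                opts += list(product(males[k], females[k]))
            options.append(opts)
        for assignment in product(*options):
            individuals = []
            for k, parents in enumerate(assignment):
                fa, mo = (None, None) if parents is None else parents
                individuals.append(
                    Individual(
                        individual_id=f"I{k}",
                        family_id="FAM",
                        father_id=None if fa is None else f"I{fa}",
                        mother_id=None if mo is None else f"I{mo}",
                        sex=sexes[k],
                    )
                )
            yield individuals


# ------------------------------------------------------------ T^2 and CMC

def t2_exact(case_rows, control_rows):
    """Generalized T^2 on integer dosage fixtures in exact rational arithmetic.

    Requires the pooled within-group covariance to be nonsingular.
    """
    A = sympy.Matrix(case_rows)
    U = sympy.Matrix(control_rows)
    na, nu = A.rows, U.rows
    n = na + nu
    mean_a = sympy.Matrix([sympy.Rational(sum(A[:, j]), na) for j in range(A.cols)])
    mean_u = sympy.Matrix([sympy.Rational(sum(U[:, j]), nu) for j in range(U.cols)])
    d = mean_a - mean_u
    Za = A - sympy.ones(na, 1) * mean_a.T
    Zu = U - sympy.ones(nu, 1) * mean_u.T
    S = (Za.T * Za + Zu.T * Zu) / (n - 2)
    stat = sympy.Rational(na * nu, n) * (d.T * S.inv() * d)[0, 0]
    return stat


def cmc_collapse_exact(rows, mafs, threshold):
    """Hand collapse: columns with maf < threshold become one carrier flag."""
    rows = [list(r) for r in rows]
    m = len(mafs)
    rare = [j for j in range(m) if mafs[j] < threshold]
    common = [j for j in range(m) if j not in rare]
    out = []
    for r in rows:
        collapsed = [r[j] for j in common]
        if rare:
            collapsed.append(1 if any(r[j] > 0 for j in rare) else 0)
        out.append(collapsed)
    return out


def pearson_chi2_exact(a, b, c, d):
    """Pearson 2x2 chi-square in exact rationals."""
    a, b, c, d = (Fraction(x) for x in (a, b, c, d))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return Fraction(0)
    return n * (a * d - b * c) ** 2 / denom


def t2_permutation_pvalue(dosage, n_cases, observed_stat, n_perm, seed, chunk=10000):
    """Monte-Carlo p-value of the uncorrected T^2 under label permutation.

    Re-derives the statistic for every permuted case assignment with
    closed-form batched linear algebra (pooled covariance from the fixed
    Gram matrix), independent of the package's implementation.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(dosage, dtype=float)
    n, m = X.shape
    nu = n - n_cases
    G = X.T @ X
    count = 0
    for start in range(0, n_perm, chunk):
        b = min(chunk, n_perm - start)
        r = rng.random((b, n))
        order = np.argsort(r, axis=1)
        mask = np.zeros((b, n), dtype=float)
        np.put_along_axis(mask, order[:, :n_cases], 1.0, axis=1)
        a = (mask @ X) / n_cases
        u = ((1.0 - mask) @ X) / nu
        S = (
            G[None, :, :]
            - n_cases * np.einsum("bi,bj->bij", a, a)
            - nu * np.einsum("bi,bj->bij", u, u)
        ) / (n - 2)
        d = a - u
        stat = (n_cases * nu / n) * np.einsum("bi,bij,bj->b", d, np.linalg.inv(S), d)
        count += int((stat >= observed_stat - 1e-12).sum())
    return count / n_perm


# ----------------------------------------------------------------- FPCA

def fpca_oracle(matrix, case_ids, control_ids, pcorr, variance_explained=0.85,
                n_basis_max=10, n_grid=101):
    """Brute-force FPCA statistic with explicit dense linear algebra.

    Normal-equation smoothing, eigendecomposition of the grid covariance via
    numpy.linalg.eigh, and explicit per-component loops.
    """
    pos = np.array([v.pos for v in matrix.variants], dtype=float)
    t = (pos - pos.min()) / (pos.max() - pos.min())
    m = len(pos)
    nb = min(m, n_basis_max)
    order = min(4, nb)
    degree = order - 1
    internal = nb - order
    knots = np.concatenate([
        np.zeros(order), np.arange(1, internal + 1) / (internal + 1), np.ones(order)
    ])

    def design(x):
        cols = []
        for i in range(nb):
            coef = np.zeros(nb)
            coef[i] = 1.0
            cols.append(BSpline(knots, coef, degree, extrapolate=False)(x))
        return np.column_stack(cols)

    Phi = design(t)
    grid = np.linspace(0, 1, n_grid)
    Bg = design(grid)

    n = matrix.n_individuals
    coeffs = np.empty((n, nb))
    PtP_inv = np.linalg.inv(Phi.T @ Phi)
    for i in range(n):
        coeffs[i] = PtP_inv @ Phi.T @ matrix.dosage[i]
    Z = coeffs @ Bg.T
    Zc = Z - Z.mean(axis=0)
    C = (Zc.T @ Zc) / (n - 1)
    evals, evecs = np.linalg.eigh(C)
    idx = np.argsort(evals)[::-1]
    evals, evecs = evals[idx], evecs[:, idx]
    total = evals[evals > 0].sum()
    cum = np.cumsum(evals) / total
    k = int(np.searchsorted(cum, variance_explained) + 1)
    k = min(k, int((evals > 1e-12 * evals[0]).sum()))

    rows_a = matrix.rows(case_ids)
    rows_u = matrix.rows(control_ids)
    na, nu = len(rows_a), len(rows_u)
    stat = 0.0
    for comp in range(k):
        s = Zc @ evecs[:, comp]
        sa, su = s[rows_a], s[rows_u]
        lam = (((sa - sa.mean()) ** 2).sum() + ((su - su.mean()) ** 2).sum()) / (n - 2)
        stat += (sa.mean() - su.mean()) ** 2 / lam
    stat *= na * nu / n
    return stat / float(getattr(pcorr, "value", pcorr)), k
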