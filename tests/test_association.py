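import numpy as np
import pytest
from scipy import stats

from _oracles import (
    cmc_collapse_exact,
    fpca_oracle,
    pearson_chi2_exact,
    t2_exact,
    t2_permutation_pvalue,
)
from famseq_assoc.association import (
    GeneAssociation,
    GeneSkipped,
    chi_min_family,
    cmc_collapse,
    cmc_family,
    fpca_family,
    t2_family,
)
from famseq_assoc.genotypes import finalize_matrix
from famseq_assoc.pedigree import Individual

# 8 individuals x 2 variants; first 4 are cases
T2_FIXTURE = np.array(
    [[0, 1], [1, 2], [2, 1], [1, 1], [0, 0], [1, 1], [0, 1], [2, 2]], dtype=float
)


def _ids(n):
    return [f"i{k}" for k in range(n)]


def _split(mat, n_cases):
    return mat.ids[:n_cases], mat.ids[n_cases:]


class TestT2:
    def test_matches_exact_rational_oracle(self, matrix_factory):
        mat = matrix_factory(T2_FIXTURE)
        cases, controls = _split(mat, 4)
        result = t2_family(mat, cases, controls, 1.0)
        oracle = float(t2_exact(T2_FIXTURE[:4].astype(int).tolist(),
                                T2_FIXTURE[4:].astype(int).tolist()))
        assert result.statistic == pytest.approx(oracle, abs=1e-10)
        assert result.df == 2

    def test_identical_group_means_give_zero_statistic(self, matrix_factory):
        block = np.array([[0, 1], [1, 0], [2, 2], [1, 1]], dtype=float)
        mat = matrix_factory(np.vstack([block, block]))
        cases, controls = _split(mat, 4)
        result = t2_family(mat, cases, controls, 1.0)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_pvalue_matches_permutation_reference(self, rng):
        n, m = 500, 3
        X = rng.binomial(2, [0.3, 0.2, 0.4], size=(n, m)).astype(float)
        # mild association so the observed p is informative
        score = X @ [0.4, 0.3, 0.3]
        y = rng.random(n) < 1 / (1 + np.exp(1.0 - 0.35 * score))
        ids = _ids(n)
        mat = finalize_matrix(ids, [("1", j + 101, "A", "T") for j in range(m)], X)
        cases = [ids[i] for i in np.flatnonzero(y)]
        controls = [ids[i] for i in np.flatnonzero(~y)]
        result = t2_family(mat, cases, controls, 1.0)
        p_perm = t2_permutation_pvalue(
            mat.dosage[np.r_[mat.rows(cases), mat.rows(controls)]],
            len(cases),
            result.statistic,
            n_perm=100_000,
            seed=7,
        )
        # Monte-Carlo error (3 SE at 1e5 draws) plus a small n=500 asymptotic allowance
        tol = 3 * np.sqrt(max(p_perm * (1 - p_perm), 1e-6) / 100_000) + 0.005
        assert result.p_value == pytest.approx(p_perm, abs=tol)

    def test_invariant_to_column_and_row_order(self, matrix_factory, rng):
        X = rng.binomial(2, [0.3, 0.4, 0.2], size=(30, 3)).astype(float)
        mat = matrix_factory(X)
        cases, controls = _split(mat, 15)
        base = t2_family(mat, cases, controls, 1.0)
        flipped = matrix_factory(X[:, ::-1], positions=[130, 120, 110])
        assert t2_family(flipped, cases, controls, 1.0).statistic == pytest.approx(
            base.statistic, rel=1e-9
        )
        assert t2_family(mat, cases[::-1], controls[::-1], 1.0).statistic == pytest.approx(
            base.statistic, rel=1e-12
        )

    def test_small_group_is_argument_error(self, matrix_factory):
        mat = matrix_factory(T2_FIXTURE)
        with pytest.raises(ValueError):
            t2_family(mat, mat.ids[:1], mat.ids[1:], 1.0)


class TestCMC:
    def test_collapse_indicator_definition(self, matrix_factory):
        # columns with sample MAF < 0.25 are rare here
        raw = np.array([[0, 1], [0, 0], [1, 0], [0, 0], [0, 0], [0, 0]], dtype=float)
        mat = matrix_factory(raw)
        out = cmc_collapse(mat, rare_threshold=0.25)
        assert out.n_variants == 1
        assert np.allclose(out.dosage[:, 0], [1, 0, 1, 0, 0, 0])

    def test_no_rare_columns_is_identity(self, matrix_factory, rng):
        mat = matrix_factory(rng.binomial(2, [0.4, 0.3], size=(20, 2)).astype(float))
        out = cmc_collapse(mat, rare_threshold=0.01)
        assert out is mat

    def test_three_rare_two_common_gives_three_columns(self, rng, matrix_factory):
        n = 60
        X = np.zeros((n, 5))
        X[:, 0] = rng.binomial(2, 0.4, n)
        X[:, 1] = rng.binomial(2, 0.35, n)
        for j in (2, 3, 4):
            X[rng.integers(0, n), j] = 1  # singletons: rare
        mat = matrix_factory(X)
        assert mat.n_variants == 5
        out = cmc_collapse(mat, rare_threshold=0.05)
        assert out.n_variants == 3
        assert out.variants[-1].alt == "<CARRIER>"

    def test_family_statistic_matches_hand_collapsed_oracle(self, matrix_factory):
        raw = np.array(
            [
                [1, 0, 0, 2, 1],
                [0, 1, 0, 1, 0],
                [0, 0, 0, 0, 1],
                [2, 0, 1, 1, 2],
                [0, 0, 0, 2, 0],
                [1, 0, 0, 0, 1],
                [0, 0, 0, 1, 2],
                [0, 1, 0, 1, 0],
                [1, 0, 0, 2, 1],
                [0, 0, 1, 0, 0],
            ],
            dtype=float,
        )
        mat = matrix_factory(raw)
        mafs = [v.maf for v in mat.variants]
        threshold = 0.2
        collapsed = cmc_collapse_exact(raw.astype(int).tolist(), mafs, threshold)
        oracle = float(t2_exact(collapsed[:5], collapsed[5:]))
        result = cmc_family(mat, mat.ids[:5], mat.ids[5:], 1.0, rare_threshold=threshold)
        assert result.statistic == pytest.approx(oracle, abs=1e-10)

    def test_equals_t2_when_no_rare(self, matrix_factory, rng):
        mat = matrix_factory(rng.binomial(2, [0.4, 0.3, 0.25], size=(40, 3)).astype(float))
        t2 = t2_family(mat, mat.ids[:20], mat.ids[20:], 1.0)
        cmc = cmc_family(mat, mat.ids[:20], mat.ids[20:], 1.0, rare_threshold=0.01)
        assert cmc.statistic == t2.statistic and cmc.df == t2.df

    def test_only_rare_reduces_to_one_dof_carrier_test(self, rng, matrix_factory):
        n = 50
        X = np.zeros((n, 3))
        for j in range(3):
            X[rng.choice(n, 2, replace=False), j] = 1
        mat = matrix_factory(X)
        result = cmc_family(mat, mat.ids[:25], mat.ids[25:], 1.0, rare_threshold=0.5)
        assert result.df == 1
        carrier = (mat.dosage > 0).any(axis=1).astype(float)
        ind_mat = finalize_matrix(mat.ids, [("1", 101, "A", "T")], carrier[:, None])
        expected = t2_family(ind_mat, mat.ids[:25], mat.ids[25:], 1.0)
        assert result.statistic == pytest.approx(expected.statistic, rel=1e-12)


class TestFPCA:
    def test_matches_dense_oracle(self, rng, matrix_factory):
        X = rng.binomial(2, [0.3, 0.1, 0.4, 0.2, 0.35, 0.25], size=(40, 6)).astype(float)
        mat = matrix_factory(X, positions=[105, 130, 131, 160, 180, 199])
        cases, controls = _split(mat, 20)
        result = fpca_family(mat, cases, controls, 1.0, variance_explained=0.85)
        oracle_stat, oracle_k = fpca_oracle(mat, cases, controls, 1.0, 0.85)
        assert result.df == oracle_k
        assert result.statistic == pytest.approx(oracle_stat, rel=1e-8)

    def test_identical_groups_give_zero(self, matrix_factory):
        block = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0], [1, 1, 1]], dtype=float)
        mat = matrix_factory(np.vstack([block, block]))
        result = fpca_family(mat, mat.ids[:4], mat.ids[4:], 1.0)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_fewer_than_three_variants_is_skip(self, matrix_factory, rng):
        mat = matrix_factory(rng.binomial(2, [0.3, 0.4], size=(20, 2)).astype(float))
        with pytest.raises(GeneSkipped):
            fpca_family(mat, mat.ids[:10], mat.ids[10:], 1.0)


class TestChiMin:
    def test_pearson_fixture_matches_hand_formula(self, matrix_factory):
        # cases: 20 individuals carrying 10 minor alleles; controls: 5 of 40
        case_dos = np.zeros(20)
        case_dos[:10] = 1
        control_dos = np.zeros(20)
        control_dos[:5] = 1
        mat = matrix_factory(np.concatenate([case_dos, control_dos])[:, None])
        result = chi_min_family(mat, mat.ids[:20], mat.ids[20:], 1.0)
        expected = float(pearson_chi2_exact(10, 30, 5, 35))
        assert expected == pytest.approx(2.051282, abs=1e-6)
        assert result.statistic == pytest.approx(expected, abs=1e-10)
        assert result.df == 1

    def test_reports_minimum_per_variant_p(self, rng, matrix_factory):
        X = rng.binomial(2, [0.3, 0.2, 0.4, 0.15], size=(60, 4)).astype(float)
        mat = matrix_factory(X)
        cases, controls = _split(mat, 30)
        result = chi_min_family(mat, cases, controls, 1.0)
        per_variant = []
        for j in range(mat.n_variants):
            a, b = (float(mat.dosage[mat.rows(cases), j].sum()),
                    2.0 * 30 - float(mat.dosage[mat.rows(cases), j].sum()))
            c, d = (float(mat.dosage[mat.rows(controls), j].sum()),
                    2.0 * 30 - float(mat.dosage[mat.rows(controls), j].sum()))
            per_variant.append(stats.chi2.sf(float(pearson_chi2_exact(a, b, c, d)), 1))
        assert result.p_value == pytest.approx(min(per_variant), abs=1e-12)
        assert all(result.p_value <= p + 1e-15 for p in per_variant)

    def test_sidak_adjustment_is_monotone(self, rng, matrix_factory):
        X = rng.binomial(2, [0.3, 0.2, 0.4], size=(40, 3)).astype(float)
        mat = matrix_factory(X)
        cases, controls = _split(mat, 20)
        raw = chi_min_family(mat, cases, controls, 1.0)
        adj = chi_min_family(mat, cases, controls, 1.0, sidak=True)
        assert adj.p_value >= raw.p_value


@pytest.mark.parametrize("c", [1.5, 2.0, 3.7])
def test_all_statistics_scale_inversely_with_pcorr(rng, matrix_factory, c):
    X = rng.binomial(2, [0.3, 0.05, 0.4, 0.2], size=(50, 4)).astype(float)
    mat = matrix_factory(X)
    cases, controls = mat.ids[:25], mat.ids[25:]
    for fn in (
        lambda p: t2_family(mat, cases, controls, p),
        lambda p: cmc_family(mat, cases, controls, p, 0.1),
        lambda p: fpca_family(mat, cases, controls, p),
        lambda p: chi_min_family(mat, cases, controls, p),
    ):
        assert fn(c).statistic == pytest.approx(fn(1.0).statistic / c, rel=1e-10)


def test_single_variant_gene_consistency(rng, matrix_factory):
    X = rng.binomial(2, 0.3, size=(60, 1)).astype(float)
    mat = matrix_factory(X)
    cases, controls = _split(mat, 30)
    t2 = t2_family(mat, cases, controls, 1.0)
    cmc = cmc_family(mat, cases, controls, 1.0, rare_threshold=0.01)
    chimin = chi_min_family(mat, cases, controls, 1.0)
    assert t2.df == cmc.df == chimin.df == 1
    assert cmc.statistic == t2.statistic
    # the genotype-based 1-df T^2 and the allelic chi-square agree closely
    # for a common variant near Hardy-Weinberg proportions
    assert chimin.statistic == pytest.approx(t2.statistic, rel=0.25, abs=0.5)


def test_null_pvalues_are_uniform():
    """T2F/CMCF p-values pass a KS uniformity check under the unrelated null
    (500 individuals, 1000 genes of independent common variants)."""
    rng = np.random.default_rng(7)
    n = 500
    ids = _ids(n)
    pvals = {"t2f": [], "cmcf": []}
    for _ in range(1000):
        m = 6
        X = rng.binomial(2, rng.uniform(0.05, 0.5, m), size=(n, m)).astype(float)
        mat = finalize_matrix(ids, [("1", j + 101, "A", "T") for j in range(m)], X)
        y = rng.binomial(1, 0.5, n)
        cases = [ids[i] for i in np.flatnonzero(y == 1)]
        controls = [ids[i] for i in np.flatnonzero(y == 0)]
        pvals["t2f"].append(t2_family(mat, cases, controls, 1.0).p_value)
        pvals["cmcf"].append(cmc_family(mat, cases, controls, 1.0).p_value)
    for method, p in pvals.items():
        assert stats.kstest(p, "uniform").pvalue > 0.01, method


class TestModelInterface:
    def test_fit_runs_all_methods_and_summarizes(self, rng, matrix_factory):
        X = rng.binomial(2, [0.3, 0.2, 0.4, 0.1], size=(40, 4)).astype(float)
        mat = matrix_factory(X)
        model = GeneAssociation(mat, mat.ids[:20], mat.ids[20:], 1.0)
        fit = model.fit()
        assert set(fit.results) == {"t2f", "cmcf", "fpcaf", "chimin"}
        assert set(fit.pvalues) == set(fit.results)
        text = fit.summary()
        assert "T2F" in text and "P_corr" in text

    def test_fpca_skip_is_recorded_not_raised(self, rng, matrix_factory):
        X = rng.binomial(2, [0.3, 0.2], size=(30, 2)).astype(float)
        mat = matrix_factory(X)
        fit = GeneAssociation(mat, mat.ids[:15], mat.ids[15:], 1.0).fit()
        assert "fpcaf" in fit.skipped and "fpcaf" not in fit.results

    def test_from_pedigree_computes_correction(self, rng, matrix_factory):
        inds = []
        for fam in range(10):
            f = f"F{fam}"
            inds += [
                Individual(f"{f}d", f, None, None, "male"),
                Individual(f"{f}m", f, None, None, "female"),
                Individual(f"{f}c1", f, f"{f}d", f"{f}m", "male"),
                Individual(f"{f}c2", f, f"{f}d", f"{f}m", "female"),
            ]
        ids = [i.individual_id for i in inds]
        X = rng.binomial(2, [0.3, 0.4, 0.25], size=(len(ids), 3)).astype(float)
        mat = finalize_matrix(ids, [("1", j + 101, "A", "T") for j in range(3)], X)
        cases = [i for i in ids if i.endswith("c1")]
        controls = [i for i in ids if i.endswith("d")]
        model = GeneAssociation.from_pedigree(mat, inds, cases, controls)
        assert model.pcorr.value != pytest.approx(1.0)
        fit = model.fit(methods=("t2f",))
        assert fit.results["t2f"].p_corr_applied == pytest.approx(model.pcorr.value)
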