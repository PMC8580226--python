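import numpy as np
import pandas as pd
import pytest

from skincomet import skinstats
from skincomet.seqio import LabeledMatrix, ModuleDef, ValidationError
from skincomet.skinstats import (EIGHT_MEASUREMENTS, compute_sa_score,
                                 pathway_lm, pathway_scores, rda,
                                 rowmax_normalize, top_arrows, order_by_sa)


def _pheno(values, subjects=None):
    subjects = subjects or [f"s{i}" for i in range(len(values))]
    return pd.DataFrame(values, index=subjects, columns=list(EIGHT_MEASUREMENTS))


class TestSaScore:
    def test_identical_subjects_all_zero(self):
        sa = compute_sa_score(_pheno(np.ones((4, 8))))
        assert (sa == 0).all()

    def test_uniformly_extreme_subject_ranks_highest(self, rng):
        vals = rng.normal(0, 1, size=(10, 8))
        vals[3] = vals.max(axis=0) + 1.0
        vals[3, 5] = vals[:, 5].min() - 1.0  # evenness: low = old-looking
        sa = compute_sa_score(_pheno(vals))
        assert sa.idxmax() == "s3"

    def test_orientation_flip_negates_column_contribution(self, rng):
        vals = rng.normal(0, 1, size=(8, 8))
        base = compute_sa_score(_pheno(vals))
        orient = dict(skinstats.DEFAULT_ORIENTATION)
        orient["roughness"] = -1
        flipped = compute_sa_score(_pheno(vals), orientation=orient)
        col = _pheno(vals)["roughness"]
        z = (col - col.mean()) / col.std(ddof=1)
        np.testing.assert_allclose(base - flipped, 2 * z / 8, atol=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        vals = rng.normal(0, 1, size=(9, 8))
        pheno = _pheno(vals)
        scaled = pheno.copy()
        scaled["roughness"] = scaled["roughness"] * 12.5 + 40.0
        np.testing.assert_allclose(compute_sa_score(pheno),
                                   compute_sa_score(scaled), atol=1e-12)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            compute_sa_score(_pheno(np.ones((2, 8))))


def _brute_force_var_explained(Y, x):
    """Independent oracle: summed per-column univariate regression SS over
    total SS, on the centered response."""
    Yc = Y - Y.mean(axis=0)
    xc = x - x.mean()
    ss_fit = 0.0
    for j in range(Yc.shape[1]):
        beta = np.dot(xc, Yc[:, j]) / np.dot(xc, xc)
        ss_fit += np.sum((beta * xc) ** 2)
    return ss_fit / np.sum(Yc ** 2)


class TestRda:
    def test_orthogonal_constraint_explains_nothing(self):
        n = 8
        x = np.array([1.0, -1.0] * 4)
        col = np.arange(n, dtype=float)
        col -= col.mean()
        col -= (col @ x) / (x @ x) * x  # orthogonalize
        Y = pd.DataFrame({"a": col, "b": 2 * col})
        res = rda(Y, x, transform="none", n_perm=9, seed=1)
        assert res.var_explained == pytest.approx(0.0, abs=1e-12)

    def test_rank_one_construction_fully_explained(self, rng):
        n = 12
        x = rng.normal(0, 1, n)
        load = rng.normal(0, 1, 5)
        Y = pd.DataFrame(np.outer(x - x.mean(), load))
        res = rda(Y, x, transform="none", n_perm=9, seed=1)
        assert res.var_explained == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n, p = int(rng.integers(5, 30)), int(rng.integers(2, 20))
            Y = rng.random((n, p))
            x = rng.normal(0, 1, n)
            res = rda(pd.DataFrame(Y), x, transform="none", n_perm=1, seed=0)
            assert res.var_explained == pytest.approx(
                _brute_force_var_explained(Y, x), abs=1e-9)

    def test_decomposition_sums(self, rng):
        Y = rng.random((15, 6))
        x = rng.normal(0, 1, 15)
        res = rda(pd.DataFrame(Y), x, transform="hellinger", n_perm=9, seed=0)
        assert 0.0 <= res.var_explained <= 1.0
        # pseudo-F consistent with the decomposition
        ve = res.var_explained
        f = (ve / 1) / ((1 - ve) / (15 - 2))
        assert res.pseudo_f == pytest.approx(f, rel=1e-9)

    def test_perm_p_invariant_to_affine_constraint_rescale(self, rng):
        Y = rng.random((16, 5))
        x = rng.normal(0, 1, 16)
        r1 = rda(pd.DataFrame(Y), x, n_perm=99, seed=42)
        r2 = rda(pd.DataFrame(Y), 3.5 * x - 7.0, n_perm=99, seed=42)
        assert r1.perm_p == r2.perm_p
        assert r1.var_explained == pytest.approx(r2.var_explained, abs=1e-12)

    def test_constant_constraint_rejected(self, rng):
        Y = pd.DataFrame(rng.random((6, 3)))
        with pytest.raises(ValidationError, match="constant"):
            rda(Y, np.ones(6), n_perm=9, seed=0)

    def test_group_indicator_constraint(self, rng):
        Y = rng.random((20, 8))
        groups = np.array([0.0] * 10 + [1.0] * 10)
        Y[10:, 0] += 2.0  # planted group effect on one feature
        res = rda(pd.DataFrame(Y), groups, transform="none", n_perm=199, seed=3)
        assert res.perm_p < 0.05
        assert abs(res.arrow_scores.iloc[0]) == res.arrow_scores.abs().max()


class TestTopArrows:
    def _result(self, scores):
        return skinstats.RdaResult(0.5, 1.0, 0.05,
                                   pd.Series(dtype=float),
                                   pd.Series(scores), 99, 0)

    def test_ranked_by_absolute_loading(self):
        res = self._result({"a": 0.1, "b": -0.9, "c": 0.5})
        assert top_arrows(res, 2) == [("b", -0.9), ("c", 0.5)]

    def test_k_larger_than_variables_warns_and_returns_all(self):
        res = self._result({"a": 0.1, "b": -0.9})
        with pytest.warns(UserWarning):
            out = top_arrows(res, 5)
        assert len(out) == 2

    def test_zero_loading_never_precedes_nonzero(self):
        res = self._result({"a": 0.0, "b": 0.2})
        assert top_arrows(res, 2)[0][0] == "b"


class TestPathwayScores:
    def test_histidine_sum(self):
        catalog = [ModuleDef("Histidine metabolism", "hist",
                             ("hutH", "hutU", "hutL"))]
        genes = pd.DataFrame({"hutH": [2.0], "hutU": [1.0], "hutL": [0.0]},
                             index=["s1"])
        out = pathway_scores(genes, catalog)
        assert out.loc["s1", "Histidine metabolism"] == 3.0

    def test_zero_table_zero_pathways(self):
        catalog = [ModuleDef("P", "p", ("a", "b"))]
        genes = pd.DataFrame({"a": [0.0], "b": [0.0]}, index=["s1"])
        assert (pathway_scores(genes, catalog) == 0).all().all()

    def test_row_mass_conserved_under_partition(self, rng):
        catalog = [ModuleDef("P1", "p1", ("a", "b")), ModuleDef("P2", "p2", ("c",))]
        genes = pd.DataFrame(rng.random((4, 3)), columns=["a", "b", "c"])
        out = pathway_scores(genes, catalog)
        np.testing.assert_allclose(out.sum(axis=1), genes.sum(axis=1))


class TestPathwayLm:
    def test_exact_fit_recovered(self):
        sa = pd.Series(np.linspace(-2, 2, 10), index=[f"s{i}" for i in range(10)])
        scores = pd.DataFrame({"P": 2.0 * sa + 1.0})
        res = pathway_lm(scores, sa)[0]
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_fdr_adds_qvalues(self, rng):
        sa = pd.Series(rng.normal(0, 1, 20), index=[f"s{i}" for i in range(20)])
        scores = pd.DataFrame({f"P{j}": rng.normal(0, 1, 20) for j in range(4)},
                              index=sa.index)
        res = pathway_lm(scores, sa, fdr=True)
        assert all(r.q_value is not None and r.q_value >= r.p_value - 1e-12
                   for r in res)

    def test_too_few_subjects_rejected(self):
        sa = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        scores = pd.DataFrame({"P": [1.0, 2.0, 3.0]}, index=list("abc"))
        with pytest.raises(ValidationError):
            pathway_lm(scores, sa)


class TestRowmaxNormalize:
    def test_rows_scaled_to_unit_max(self):
        df = pd.DataFrame([[3.0, 6.0, 0.0], [0.0, 0.0, 0.0]],
                          index=["p1", "p2"], columns=["a", "b", "c"])
        out = rowmax_normalize(df)
        np.testing.assert_allclose(out.df.loc["p1"], [0.5, 1.0, 0.0])
        assert (out.df.loc["p2"] == 0).all()

    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.random((3, 5)))
        once = rowmax_normalize(df)
        twice = rowmax_normalize(once.df)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_subjects_orderable_by_sa(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p"],
                          columns=["s1", "s2", "s3"])
        sa = pd.Series({"s1": 0.5, "s2": -1.0, "s3": 0.1})
        ordered = order_by_sa(df, sa)
        assert list(ordered.columns) == ["s2", "s3", "s1"]
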