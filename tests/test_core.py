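"""Unit tests for centering, training, axis fitting, projection, scaling
and classification."""

import numpy as np
import pandas as pd
import pytest

from _util import (align_columns, duplicate_items, fit_from_centered,
                   grouped_design, per_sample_groups, random_centered,
                   zero_reference)
from depca import core
from depca.errors import DataError, UsageError


def em(values, items, samples):
    return core.ExpressionMatrix(
        values=pd.DataFrame(values, index=items, columns=samples))


# ---------------------------------------------------------------------------
# reference and centering
# ---------------------------------------------------------------------------

class TestComputeReference:
    def test_control_group_mean(self):
        m = em([[1.0, 3.0], [2.0, 2.0]], ["g1", "g2"], ["a", "b"])
        d = core.Design(group_of={"a": "ctrl", "b": "ctrl"},
                        reference_rule=core.CONTROL_GROUP,
                        control_label="ctrl")
        r = core.compute_reference(m, d)
        assert r.r.to_dict() == {"g1": 2.0, "g2": 2.0}
        assert r.provenance == "control_group:ctrl"

    def test_grand_mean_of_identical_samples_is_that_sample(self):
        v = [1.5, -2.0, 0.25]
        m = em(np.tile(np.array(v)[:, None], (1, 4)),
               ["g1", "g2", "g3"], list("abcd"))
        r = core.compute_reference(m, core.Design(
            group_of={s: "g" for s in "abcd"}))
        np.testing.assert_array_equal(r.r.to_numpy(), v)

    def test_grand_mean_matches_explicit_summation(self):
        # 10-group time course, 4 samples each: brute-force per-item mean
        rng = np.random.default_rng(7)
        samples = [f"t{g}_r{k}" for g in range(10) for k in range(4)]
        vals = rng.normal(size=(25, 40))
        m = em(vals, [f"i{l}" for l in range(25)], samples)
        d = core.Design(group_of={s: s.split("_")[0] for s in samples})
        r = core.compute_reference(m, d)
        oracle = np.array([sum(row) / len(row) for row in vals])
        np.testing.assert_allclose(r.r.to_numpy(), oracle, rtol=0, atol=1e-12)

    def test_all_missing_item_flagged_and_zeroed(self):
        m = em([[np.nan, np.nan], [1.0, 3.0]], ["g1", "g2"], ["a", "b"])
        r = core.compute_reference(m, core.Design(group_of={"a": "g", "b": "g"}))
        assert r.r["g1"] == 0.0
        assert r.undefined_items == {"g1"}
        X = core.center(m, r)
        assert X.excluded_items == frozenset({"g1"})
        assert X.m_f == 1

    def test_control_rule_without_control_samples_errors(self):
        with pytest.raises(DataError, match="ctrl"):
            core.Design(group_of={"a": "g"},
                        reference_rule=core.CONTROL_GROUP,
                        control_label="ctrl")


class TestCenter:
    def test_elementwise_subtraction_and_transpose(self):
        # two samples x two items, reference (1, 1)
        m = em([[2.0, 4.0], [3.0, 5.0]], ["g1", "g2"], ["s1", "s2"])
        r = core.ReferenceVector(r=pd.Series({"g1": 1.0, "g2": 1.0}),
                                 provenance="test")
        X = core.center(m, r)
        assert X.sample_ids == ["s1", "s2"] and X.item_ids == ["g1", "g2"]
        np.testing.assert_array_equal(X.X.to_numpy(), [[1.0, 2.0], [3.0, 4.0]])

    def test_sample_equal_to_reference_is_all_zero_row(self):
        m = em([[5.0, 1.0], [6.0, 2.0]], ["g1", "g2"], ["ref_like", "other"])
        r = core.ReferenceVector(r=pd.Series({"g1": 5.0, "g2": 6.0}),
                                 provenance="test")
        X = core.center(m, r)
        assert (X.X.loc["ref_like"] == 0.0).all()

    @pytest.mark.parametrize("ref_value", [-3.0, 0.0, 17.5])
    def test_missing_cell_becomes_exact_zero(self, ref_value):
        m = em([[np.nan, 2.0]], ["g1"], ["s1", "s2"])
        r = core.ReferenceVector(r=pd.Series({"g1": ref_value}),
                                 provenance="test")
        X = core.center(m, r)
        assert X.X.loc["s1", "g1"] == 0.0
        assert X.m_f == 1  # per-sample missing cells do not reduce m_f

    def test_reference_missing_item_errors_with_item_list(self):
        m = em([[1.0]], ["g1"], ["s1"])
        r = core.ReferenceVector(r=pd.Series({"other": 0.0}), provenance="t")
        with pytest.raises(DataError, match="g1"):
            core.center(m, r)


class TestZeroOutItems:
    def test_empty_set_is_identity(self):
        X = random_centered(np.random.default_rng(0), 3, 5)
        X2 = core.zero_out_items(X, set())
        pd.testing.assert_frame_equal(X.X, X2.X)
        assert X2.m_f == X.m_f

    def test_zeroing_half_of_items_updates_m_f(self):
        X = random_centered(np.random.default_rng(0), 4, 12)
        victims = set(X.item_ids[:6])
        X2 = core.zero_out_items(X, victims)
        assert X2.m_f == 6
        assert (X2.X[sorted(victims)].to_numpy() == 0.0).all()
        assert X2.X.shape == X.X.shape

    def test_projection_drops_exactly_the_zeroed_terms(self):
        # term-by-term dot-product oracle on a fixed axis model
        rng = np.random.default_rng(3)
        X = random_centered(rng, 6, 20)
        model, _ = fit_from_centered(X, grouped_design(X, 3))
        S = set(X.item_ids[4:9])
        Y1 = core.project_samples(X, model).scores.to_numpy()
        Y2 = core.project_samples(core.zero_out_items(X, S), model)
        dropped = np.zeros_like(Y1)
        V = model.V
        for k, s in enumerate(X.sample_ids):
            for j in range(model.n_axes):
                dropped[k, j] = sum(X.X.loc[s, l] * V.loc[l].iloc[j] for l in S)
        np.testing.assert_allclose(Y2.scores.to_numpy(), Y1 - dropped,
                                   atol=1e-10)

    def test_unknown_item_errors(self):
        X = random_centered(np.random.default_rng(0), 2, 3)
        with pytest.raises(DataError, match="nope"):
            core.zero_out_items(X, {"nope"})


# ---------------------------------------------------------------------------
# training matrix
# ---------------------------------------------------------------------------

class TestBuildTraining:
    def test_group_mean_row(self):
        X = core.CenteredMatrix(X=pd.DataFrame(
            [[1.0, 3.0], [3.0, 5.0]], index=["a", "b"], columns=["i1", "i2"]))
        d = core.Design(group_of={"a": "A", "b": "A"})
        T = core.build_training(X, d)
        np.testing.assert_array_equal(T.T.to_numpy(), [[2.0, 4.0]])
        assert T.row_labels == ["A"] and T.n_t == 1

    def test_expanded_group_contributes_individual_samples(self):
        # 7 groups x 5 reps; expanding one group: 6 means + 5 samples = 11 rows
        rng = np.random.default_rng(1)
        samples = [f"g{g}_s{r}" for g in range(7) for r in range(5)]
        X = core.CenteredMatrix(X=pd.DataFrame(
            rng.normal(size=(35, 8)), index=samples,
            columns=[f"i{l}" for l in range(8)]))
        d = core.Design(group_of={s: s.split("_")[0] for s in samples})
        T = core.build_training(X, d, expand_groups={"g3"})
        assert T.n_t == 11
        assert [l for l in T.row_labels if l.startswith("g3_")] == \
            [f"g3_s{r}" for r in range(5)]

    def test_median_representative(self):
        X = core.CenteredMatrix(X=pd.DataFrame(
            [[0.0, 0.0], [0.0, 10.0], [0.0, 2.0]],
            index=["a", "b", "c"], columns=["i1", "i2"]))
        d = core.Design(group_of={s: "A" for s in "abc"})
        T = core.build_training(X, d, representative="median")
        np.testing.assert_array_equal(T.T.to_numpy(), [[0.0, 2.0]])

    def test_trimmed_mean_degrades_below_five_samples(self):
        X = random_centered(np.random.default_rng(0), 3, 4)
        d = core.Design(group_of={s: "A" for s in X.sample_ids})
        with pytest.warns(UserWarning, match="degrades"):
            T = core.build_training(X, d, representative="trimmed_mean")
        np.testing.assert_allclose(T.T.to_numpy()[0],
                                   X.X.to_numpy().mean(axis=0))

    def test_overlarge_trim_fraction_errors(self):
        X = random_centered(np.random.default_rng(0), 5, 4)
        d = core.Design(group_of={s: "A" for s in X.sample_ids})
        with pytest.raises(UsageError, match="trim"):
            core.build_training(X, d, representative="trimmed_mean",
                                trim_fraction=0.5)

    def test_group_without_samples_errors(self):
        X = random_centered(np.random.default_rng(0), 2, 3)
        d = core.Design(group_of={X.sample_ids[0]: "A", "ghost": "B",
                                  X.sample_ids[1]: "A"})
        with pytest.raises(DataError, match="B"):
            core.build_training(X, d)


# ---------------------------------------------------------------------------
# axis identification
# ---------------------------------------------------------------------------

class TestFitAxes:
    def test_diagonal_training_matrix(self):
        T = core.TrainingMatrix(T=pd.DataFrame(
            [[3.0, 0.0], [0.0, 4.0]], index=["A", "B"], columns=["i1", "i2"]))
        model = core.fit_axes(T, zero_reference(["i1", "i2"]), 2)
        np.testing.assert_allclose(model.d, [4.0, 3.0])
        np.testing.assert_allclose(np.abs(model.V.to_numpy()),
                                   [[0.0, 1.0], [1.0, 0.0]], atol=1e-12)

    def test_rank_one_training_keeps_one_axis(self):
        base = np.array([1.0, 2.0, -1.0, 0.5])
        T = core.TrainingMatrix(T=pd.DataFrame(
            np.outer([1.0, -2.0, 3.0], base),
            index=list("abc"), columns=[f"i{l}" for l in range(4)]))
        model = core.fit_axes(T, zero_reference(T.item_ids), 4)
        assert model.n_axes == 1

    def test_all_zero_training_errors(self):
        T = core.TrainingMatrix(T=pd.DataFrame(
            np.zeros((2, 3)), index=["A", "B"], columns=["i0", "i1", "i2"]))
        with pytest.raises(DataError, match="identical to reference"):
            core.fit_axes(T, zero_reference(T.item_ids), 3)

    def test_reconstruction_of_random_training_matrix(self):
        rng = np.random.default_rng(11)
        X = random_centered(rng, 7, 50)
        model, T = fit_from_centered(X)
        recon = model.U.to_numpy() @ np.diag(model.d) @ model.V.to_numpy().T
        np.testing.assert_allclose(recon, T.T.to_numpy(), atol=1e-10)
        model.validate()

    def test_training_not_recentered(self):
        # rows with a common offset: the offset must survive into the axes
        # (a grand-mean re-centering would remove it)
        T = core.TrainingMatrix(T=pd.DataFrame(
            [[2.0, 2.0], [4.0, 4.0]], index=["A", "B"], columns=["i1", "i2"]))
        model = core.fit_axes(T, zero_reference(["i1", "i2"]), 2)
        assert model.n_axes == 1  # rank 1 as given, not rank 1 re-centered to 0
        recon = model.U.to_numpy() @ np.diag(model.d) @ model.V.to_numpy().T
        np.testing.assert_allclose(recon, T.T.to_numpy(), atol=1e-12)


class TestUnifySigns:
    def _model(self, V):
        V = np.asarray(V, dtype=float)
        k = V.shape[1]
        return core.AxisModel(
            V=pd.DataFrame(V, index=[f"i{l}" for l in range(V.shape[0])],
                           columns=[f"PC{j + 1}" for j in range(k)]),
            d=np.linspace(2.0, 1.0, k),
            reference=zero_reference([f"i{l}" for l in range(V.shape[0])]),
            n_t=3, m_f=V.shape[0],
            U=pd.DataFrame(np.eye(3)[:, :k], index=list("abc"),
                           columns=[f"PC{j + 1}" for j in range(k)]))

    def test_flips_column_whose_largest_loading_is_negative(self):
        m = core.unify_signs(self._model([[0.6], [-0.8]]))
        np.testing.assert_allclose(m.V.to_numpy().ravel(), [-0.6, 0.8])

    def test_keeps_column_whose_largest_loading_is_positive(self):
        m = core.unify_signs(self._model([[0.8], [-0.6]]))
        np.testing.assert_allclose(m.V.to_numpy().ravel(), [0.8, -0.6])

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        X = random_centered(rng, 4, 9)
        model, _ = fit_from_centered(X)
        once = core.unify_signs(model)
        twice = core.unify_signs(once)
        pd.testing.assert_frame_equal(once.V, twice.V)
        pd.testing.assert_frame_equal(once.U, twice.U)

    def test_u_flipped_with_v_preserves_product(self):
        rng = np.random.default_rng(6)
        X = random_centered(rng, 5, 8)
        model, T = fit_from_centered(X)
        flipped = core.unify_signs(model)
        recon = flipped.U.to_numpy() @ np.diag(flipped.d) @ flipped.V.to_numpy().T
        np.testing.assert_allclose(recon, T.T.to_numpy(), atol=1e-10)


# ---------------------------------------------------------------------------
# projection and item components
# ---------------------------------------------------------------------------

class TestProjection:
    def test_identity_loadings_pass_scores_through(self):
        X = core.CenteredMatrix(X=pd.DataFrame(
            [[1.0, 1.0]], index=["s1"], columns=["i1", "i2"]))
        model = core.AxisModel(
            V=pd.DataFrame(np.eye(2), index=["i1", "i2"],
                           columns=["PC1", "PC2"]),
            d=np.array([1.0, 1.0]), reference=zero_reference(["i1", "i2"]),
            n_t=2, m_f=2)
        Y = core.project_samples(X, model)
        np.testing.assert_array_equal(Y.scores.to_numpy(), [[1.0, 1.0]])
        assert not Y.scaled and Y.row_kind == "samples"

    def test_all_zero_sample_lands_at_origin(self):
        rng = np.random.default_rng(2)
        X = random_centered(rng, 5, 10)
        X.X.iloc[2] = 0.0
        model, _ = fit_from_centered(X, grouped_design(X, 2))
        Y = core.project_samples(X, model)
        np.testing.assert_array_equal(Y.scores.iloc[2].to_numpy(),
                                      np.zeros(model.n_axes))

    def test_training_rows_project_to_u_times_d(self):
        rng = np.random.default_rng(8)
        X = random_centered(rng, 12, 40)
        design = grouped_design(X, 4)
        model, T = fit_from_centered(X, design)
        XT = core.CenteredMatrix(X=T.T)
        Y = core.project_samples(XT, model).scores.to_numpy()
        oracle = T.T.to_numpy() @ model.V.to_numpy()  # explicit multiplication
        np.testing.assert_allclose(Y, oracle, atol=1e-12)
        np.testing.assert_allclose(Y, model.U.to_numpy() * model.d, atol=1e-10)
        np.testing.assert_allclose(
            core.training_scores(model).scores.to_numpy(), Y, atol=1e-10)

    def test_no_item_overlap_errors(self):
        X = random_centered(np.random.default_rng(0), 2, 3)
        model, _ = fit_from_centered(X)
        other = core.CenteredMatrix(X=pd.DataFrame(
            [[1.0]], index=["s"], columns=["elsewhere"]))
        with pytest.raises(DataError, match="overlap"):
            core.project_samples(other, model)


class TestItemComponents:
    def test_diagonal_case_scores_on_own_axes(self):
        T = core.TrainingMatrix(T=pd.DataFrame(
            [[3.0, 0.0], [0.0, 4.0]], index=["A", "B"], columns=["i1", "i2"]))
        model = core.fit_axes(T, zero_reference(["i1", "i2"]), 2)
        Y = core.item_components(model, T).scores
        got = {tuple(np.round(np.abs(r), 10)) for r in Y.to_numpy()}
        assert got == {(0.0, 3.0), (4.0, 0.0)}

    def test_all_zero_item_column_lands_at_origin(self):
        rng = np.random.default_rng(4)
        X = random_centered(rng, 4, 7)
        X.X.iloc[:, 3] = 0.0
        model, T = fit_from_centered(X)
        Y = core.item_components(model, T)
        np.testing.assert_array_equal(Y.scores.iloc[3].to_numpy(),
                                      np.zeros(model.n_axes))

    def test_equals_v_times_d(self):
        rng = np.random.default_rng(9)
        X = random_centered(rng, 6, 30)
        model, T = fit_from_centered(X, grouped_design(X, 3))
        Y = core.item_components(model, T).scores.to_numpy()
        np.testing.assert_allclose(Y, model.V.to_numpy() * model.d, atol=1e-10)

    def test_mismatched_training_matrix_errors(self):
        rng = np.random.default_rng(9)
        X = random_centered(rng, 4, 6)
        model, _ = fit_from_centered(X)
        other = core.TrainingMatrix(T=pd.DataFrame(
            rng.normal(size=(3, 6)), index=list("xyz"), columns=X.item_ids))
        with pytest.raises(DataError, match="does not match"):
            core.item_components(model, other)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

class TestScaling:
    def _table(self, values, kind="samples"):
        return core.ComponentTable(
            scores=pd.DataFrame(values, columns=["PC1"]), row_kind=kind)

    def test_sample_divisor_sqrt_m_f(self):
        Z = core.scale_sample_components(self._table([[2.0]]), 4)
        assert Z.scores.iloc[0, 0] == 1.0
        assert Z.scaled and Z.scale_divisor == 2.0
        assert list(Z.scores.columns) == ["sPC1"]

    def test_m_f_one_is_identity(self):
        Z = core.scale_sample_components(self._table([[2.0]]), 1)
        assert Z.scores.iloc[0, 0] == 2.0

    def test_item_divisor_sqrt_n_t(self):
        Z = core.scale_item_components(self._table([[2.0]], "items"), 4)
        assert Z.scores.iloc[0, 0] == 1.0

    @pytest.mark.parametrize("count", [0, -1])
    def test_nonpositive_count_errors(self, count):
        with pytest.raises(UsageError):
            core.scale_sample_components(self._table([[1.0]]), count)

    def test_double_scaling_rejected(self):
        Z = core.scale_sample_components(self._table([[1.0]]), 4)
        with pytest.raises(UsageError, match="already scaled"):
            core.scale_sample_components(Z, 4)

    def test_kind_mixups_rejected(self):
        with pytest.raises(UsageError):
            core.scale_sample_components(self._table([[1.0]], "items"), 4)
        with pytest.raises(UsageError):
            core.scale_item_components(self._table([[1.0]], "samples"), 4)

    @pytest.mark.parametrize("k", [4, 9])
    def test_item_duplication_scales_sample_scores_by_sqrt_k(self, k):
        # the sqrt(m_f) growth law, via brute-force refit on duplicated items
        rng = np.random.default_rng(21)
        X = random_centered(rng, 8, 30)
        design = grouped_design(X, 4)
        model1, _ = fit_from_centered(X, design)
        Y1 = core.project_samples(X, model1).scores.to_numpy()
        Xk = duplicate_items(X, k)
        modelk, _ = fit_from_centered(Xk, design)
        Yk = core.project_samples(Xk, modelk).scores.to_numpy()
        Yk = align_columns(Y1, Yk)
        np.testing.assert_allclose(Yk, np.sqrt(k) * Y1, rtol=1e-9)
        Z1 = core.scale_sample_components(
            core.project_samples(X, model1), X.m_f).scores.to_numpy()
        Zk = align_columns(Z1, core.scale_sample_components(
            core.project_samples(Xk, modelk), Xk.m_f).scores.to_numpy())
        np.testing.assert_allclose(Zk, Z1, rtol=1e-9, atol=1e-12)

    def test_training_row_replication_scales_item_scores_by_sqrt_k(self):
        # replicate every training row k = 4 times and refit from scratch
        k = 4
        rng = np.random.default_rng(22)
        X = random_centered(rng, 5, 20)
        model1, T1 = fit_from_centered(X)
        Y1 = core.item_components(model1, T1).scores.to_numpy()
        rep = np.repeat(T1.T.to_numpy(), k, axis=0)
        labels = [f"{lab}_r{c}" for lab in T1.row_labels for c in range(k)]
        Tk = core.TrainingMatrix(T=pd.DataFrame(rep, index=labels,
                                                columns=T1.item_ids))
        modelk = core.fit_axes(Tk, zero_reference(T1.item_ids), X.m_f)
        Yk = align_columns(Y1, core.item_components(modelk, Tk).scores.to_numpy())
        np.testing.assert_allclose(Yk, np.sqrt(k) * Y1, rtol=1e-9)
        Z1 = core.scale_item_components(
            core.item_components(model1, T1), model1.n_t).scores.to_numpy()
        Zk = align_columns(Z1, core.scale_item_components(
            core.item_components(modelk, Tk), modelk.n_t).scores.to_numpy())
        np.testing.assert_allclose(Zk, Z1, rtol=1e-9, atol=1e-12)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class TestClassify:
    def _tables(self, samples, reps, labels):
        k = np.asarray(samples).shape[1]
        cols = [f"PC{j + 1}" for j in range(k)]
        st = core.ComponentTable(scores=pd.DataFrame(
            samples, index=[f"s{i}" for i in range(len(samples))],
            columns=cols), row_kind="samples")
        rt = core.ComponentTable(scores=pd.DataFrame(
            reps, index=labels, columns=cols), row_kind="samples")
        return st, rt

    def test_sample_on_representative_has_distance_zero(self):
        st, rt = self._tables([[1.0, 2.0]], [[1.0, 2.0], [0.0, 0.0]],
                              ["A", "B"])
        res = core.classify(st, rt)
        assert res.loc["s0", "label"] == "A"
        assert res.loc["s0", "distance"] == 0.0

    def test_tie_goes_to_earlier_training_row(self):
        st, rt = self._tables([[0.0]], [[1.0], [-1.0]], ["first", "second"])
        res = core.classify(st, rt)
        assert res.loc["s0", "label"] == "first"

    def test_distances_match_per_pair_euclidean_oracle(self):
        rng = np.random.default_rng(31)
        X = random_centered(rng, 12, 25)
        design = grouped_design(X, 4)
        model, _ = fit_from_centered(X, design)
        Zs = core.scale_sample_components(core.project_samples(X, model),
                                          X.m_f)
        Zt = core.scale_sample_components(core.training_scores(model), X.m_f)
        res = core.classify(Zs, Zt, n_axes_used=3)
        for s in Zs.row_ids:
            for g in Zt.row_ids:
                d = np.sqrt(sum(
                    (Zs.scores.loc[s].iloc[j] - Zt.scores.loc[g].iloc[j]) ** 2
                    for j in range(3)))
                assert res.loc[s, f"dist_{g}"] == pytest.approx(d, abs=1e-12)
            assert res.loc[s, "distance"] == min(
                res.loc[s, f"dist_{g}"] for g in Zt.row_ids)

    def test_scale_mismatch_rejected(self):
        st, rt = self._tables([[0.0]], [[1.0]], ["A"])
        Zt = core.scale_sample_components(rt, 4)
        with pytest.raises(UsageError, match="same scale"):
            core.classify(st, Zt)

    def test_excess_axis_request_rejected(self):
        st, rt = self._tables([[0.0, 1.0]], [[1.0, 0.0]], ["A"])
        with pytest.raises(UsageError, match="axes"):
            core.classify(st, rt, n_axes_used=3)
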