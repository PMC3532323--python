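import numpy as np
import pandas as pd
import pytest

from chemcca import rcca, synth
from chemcca.io import InputError, ParameterError
from chemcca.retrieval import AnnotationSet
from oracles import classical_cca


class TestFitRcca:
    def test_matches_classical_cca_oracle_unregularized(self, small_xy):
        x, y = small_xy
        model = rcca.fit_rcca(x, y, 0.0, 0.0, standardize_x=False)
        corr, u, v = classical_cca(x.to_numpy(), y.to_numpy())
        np.testing.assert_allclose(model.correlations, corr, atol=1e-8)
        for s in range(6):
            got = model.chem_variates.iloc[:, s].to_numpy()
            want = u[:, s] / u[:, s].std(ddof=1)
            agree = min(np.abs(got - want).max(), np.abs(got + want).max())
            assert agree < 1e-6

    def test_identical_views_give_unit_correlations(self, rng):
        ids = [f"c{i}" for i in range(40)]
        x = pd.DataFrame(rng.standard_normal((40, 6)), index=ids)
        model = rcca.fit_rcca(x, x.copy(), 0.0, 0.0)
        np.testing.assert_allclose(model.correlations, 1.0, atol=1e-10)

    def test_correlations_sorted_and_bounded(self, small_xy):
        x, y = small_xy
        model = rcca.fit_rcca(x, y, 0.5, 0.5)
        c = model.correlations
        assert (np.diff(c) <= 1e-12).all()
        assert (c >= 0).all() and (c <= 1).all()

    def test_training_variates_unit_variance(self, small_xy):
        x, y = small_xy
        model = rcca.fit_rcca(x, y, 0.3, 0.7)
        np.testing.assert_allclose(model.chem_variates.std(ddof=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(model.bio_variates.std(ddof=1), 1.0, atol=1e-10)

    def test_invariant_to_rotation_of_features_when_unregularized(self, small_xy, rng):
        x, y = small_xy
        base = rcca.fit_rcca(x, y, 0.0, 0.0, standardize_x=False)
        q, _ = np.linalg.qr(rng.standard_normal((x.shape[1], x.shape[1])))
        x_rot = pd.DataFrame(x.to_numpy() @ q, index=x.index)
        rot = rcca.fit_rcca(x_rot, y, 0.0, 0.0, standardize_x=False)
        np.testing.assert_allclose(base.correlations, rot.correlations, atol=1e-6)

    def test_strong_ridge_approaches_cross_covariance_svd(self, small_xy):
        x, y = small_xy
        big = 1e6
        model = rcca.fit_rcca(x, y, big, big, standardize_x=False)
        n = len(x)
        xc = x.to_numpy() - x.to_numpy().mean(0)
        yc = y.to_numpy() - y.to_numpy().mean(0)
        u, s, vt = np.linalg.svd(xc.T @ yc / (n - 1))
        w1 = model.chem_weights.iloc[:, 0].to_numpy()
        w1 = w1 / np.linalg.norm(w1)
        lead = u[:, 0] / np.linalg.norm(u[:, 0])
        assert min(np.abs(w1 - lead).max(), np.abs(w1 + lead).max()) < 1e-3

    def test_singular_unregularized_covariance_advises_ridge(self, rng):
        ids = [f"c{i}" for i in range(10)]
        x = pd.DataFrame(rng.standard_normal((10, 20)), index=ids)  # p > n
        y = pd.DataFrame(rng.standard_normal((10, 3)), index=ids)
        with pytest.raises(np.linalg.LinAlgError, match="ridge|l > 0"):
            rcca.fit_rcca(x, y, 0.0, 0.0)

    def test_nan_and_misalignment_rejected(self, small_xy):
        x, y = small_xy
        bad = x.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(InputError):
            rcca.fit_rcca(bad, y)
        with pytest.raises(InputError):
            rcca.fit_rcca(x, y.iloc[::-1])


class TestProject:
    def test_training_projection_reproduces_variates(self, small_xy):
        x, y = small_xy
        model = rcca.fit_rcca(x, y, 0.1, 0.1)
        chem, bio = rcca.project(model, x, y)
        np.testing.assert_allclose(chem.to_numpy(), model.chem_variates.to_numpy(), atol=1e-12)
        np.testing.assert_allclose(bio.to_numpy(), model.bio_variates.to_numpy(), atol=1e-12)

    def test_duplicated_row_projects_identically(self, small_xy):
        x, y = small_xy
        model = rcca.fit_rcca(x, y, 0.1, 0.1)
        dup = pd.concat([x.iloc[[0]], x.iloc[[0]]])
        chem, _ = rcca.project(model, dup, None)
        np.testing.assert_allclose(chem.iloc[0].to_numpy(), chem.iloc[1].to_numpy())

    def test_name_mismatch_rejected(self, small_xy):
        x, y = small_xy
        model = rcca.fit_rcca(x, y)
        renamed = x.rename(columns={x.columns[0]: "other"})
        with pytest.raises(InputError):
            rcca.project(model, renamed, None)


def _annotations_for(ids, n_labels=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = [(cid, f"L{rng.integers(n_labels)}", "target") for cid in ids]
    return AnnotationSet(pairs=pd.DataFrame(rows, columns=["compound_id", "label_id", "kind"]))


class TestSelectRegularization:
    def test_single_point_grid_returned(self, small_xy):
        x, y = small_xy
        ann = _annotations_for(x.index)
        l1, l2, table = rcca.select_regularization(x, y, [(0.5, 0.25)], 5, ann, seed=0)
        assert (l1, l2) == (0.5, 0.25)
        assert len(table) == 1

    def test_fold_partition_sizes(self):
        # 100 compounds over 20 folds: every fold holds exactly 5
        rng = np.random.default_rng(0)
        perm = rng.permutation(100)
        folds = [perm[i::20] for i in range(20)]
        assert all(len(f) == 5 for f in folds)

    def test_returns_grid_member_and_full_table(self, small_xy):
        x, y = small_xy
        ann = _annotations_for(x.index)
        grid = [(0.01, 0.01), (1.0, 1.0), (100.0, 100.0)]
        l1, l2, table = rcca.select_regularization(x, y, grid, 5, ann, seed=1)
        assert (l1, l2) in grid
        assert len(table) == 3
        assert table["map"].notna().all()

    def test_empty_grid_rejected(self, small_xy):
        x, y = small_xy
        with pytest.raises(ParameterError):
            rcca.select_regularization(x, y, [], 5, _annotations_for(x.index), seed=0)


class TestPermutationSignificance:
    def test_minimum_attainable_p_with_strong_signal(self):
        x, y, _ = synth.simulate_joint_data(200, 6, 5, 1, (0.9,), 0.5, seed=0)
        p, p_raw = rcca.permutation_significance(x, y, 0.01, 0.01, 1, n_perm=199, seed=1)
        assert p[0] == pytest.approx(1 / 200)
        assert p_raw[0] == 0.0

    def test_null_p_not_extreme(self):
        x, y, _ = synth.simulate_joint_data(60, 5, 4, 1, (0.0,), 1.0, seed=2)
        p, _ = rcca.permutation_significance(x, y, 0.01, 0.01, 1, n_perm=99, seed=3)
        assert p[0] > 0.01

    def test_too_few_permutations_rejected(self, small_xy):
        x, y = small_xy
        with pytest.raises(ParameterError):
            rcca.permutation_significance(x, y, 0.1, 0.1, 1, n_perm=10, seed=0)


class TestSplitSubcomponents:
    def _model_with_scores(self, scores):
        x = pd.DataFrame(
            np.diag(np.ones(len(scores))), index=[f"c{i}" for i in range(len(scores))]
        )
        model = rcca.CcaModel(
            chem_weights=pd.DataFrame(np.ones((3, 1)), columns=["comp01"]),
            bio_weights=pd.DataFrame(np.ones((3, 1)), columns=["comp01"]),
            correlations=np.array([0.9]),
            chem_variates=pd.DataFrame(
                {"comp01": scores}, index=[f"c{i}" for i in range(len(scores))]
            ),
            bio_variates=pd.DataFrame(
                {"comp01": scores}, index=[f"c{i}" for i in range(len(scores))]
            ),
            l1=0.0,
            l2=0.0,
            x_center=pd.Series(0.0, index=range(3)),
            x_scale=pd.Series(1.0, index=range(3)),
            y_center=pd.Series(0.0, index=range(3)),
            y_scale=pd.Series(1.0, index=range(3)),
        )
        return model

    def test_signs_partition_compounds(self):
        split = rcca.split_subcomponents(self._model_with_scores([2.0, -1.0, 0.5, 0.0]))
        assert split.side(0, "A") == ["c0", "c2"]
        assert split.side(0, "B") == ["c1"]  # zero-score compound joins neither

    def test_global_sign_flip_swaps_sides(self):
        m1 = self._model_with_scores([2.0, -1.0, 0.5])
        m2 = self._model_with_scores([-2.0, 1.0, -0.5])
        s1, s2 = rcca.split_subcomponents(m1), rcca.split_subcomponents(m2)
        assert s1.side(0, "A") == s2.side(0, "B")
        assert s1.side(0, "B") == s2.side(0, "A")

    def test_all_positive_scores_leave_b_empty(self):
        split = rcca.split_subcomponents(self._model_with_scores([1.0, 2.0, 3.0]))
        assert split.side(0, "B") == []


class TestRetainedComponents:
    def test_requires_pvalues_then_filters_and_truncates(self, small_xy):
        x, y = small_xy
        model = rcca.fit_rcca(x, y, 0.1, 0.1)
        with pytest.raises(InputError):
            rcca.retained_components(model)
        model.perm_pvalues = np.array([0.001, 0.2, 0.001, 0.001, 0.04, 0.9])
        assert rcca.retained_components(model, top=3) == [0, 2, 3]
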