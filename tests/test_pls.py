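"""PLS regression, LOO cross-validation, external validation, contours."""

import math

import numpy as np
import pytest

import qsar3d as q
from qsar3d.fields import FieldMatrix, GridSpec
from qsar3d.pls import loo_q2 as loo_q2_impl


def brute_force_loo(X, y, n_components):
    """Independently coded LOO loop (oracle for q^2)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = q.fit_pls(X[mask], y[mask], n_components)
        press += (y[i] - model.predict(X[i : i + 1])[0]) ** 2
    return 1.0 - press / np.sum((y - y.mean()) ** 2)


def _field_matrix(values, kinds=None):
    p = values.shape[1]
    return FieldMatrix(
        values=values,
        kinds=np.array(kinds if kinds is not None else ["steric"] * p),
        point_index=np.array([[i, 0, 0] for i in range(p)]),
        grid=GridSpec(origin=(0, 0, 0), spacing=2.0, shape=(p, 1, 1)),
    )


class TestFitPLS:
    def test_rank_one_single_component_perfect(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=10)
        X = np.outer(t, rng.normal(size=5))
        y = 2.0 * t + 1.0
        model = q.fit_pls(X, y, 1)
        assert np.allclose(model.predict(X), y, atol=1e-9)

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        model = q.fit_pls(X, y, 4)
        beta = np.linalg.lstsq(np.c_[np.ones(10), X], y, rcond=None)[0]
        assert np.allclose(model.coefficients, beta[1:], atol=1e-8)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        perm = rng.permutation(6)
        m1 = q.fit_pls(X, y, 3)
        m2 = q.fit_pls(X[:, perm], y, 3)
        assert np.allclose(m1.predict(X), m2.predict(X[:, perm]), atol=1e-9)

    def test_agrees_with_sklearn_reference(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 8))
        y = rng.normal(size=15)
        ours = q.fit_pls(X, y, 3)
        ref = PLSRegression(n_components=3, scale=False).fit(X, y[:, None])
        assert np.allclose(ours.predict(X), ref.predict(X).ravel(), atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        X = np.zeros((5, 0))
        with pytest.raises(ValueError):
            q.fit_pls(X, np.arange(5.0), 1)
        with pytest.raises(ValueError):
            q.fit_pls(np.random.default_rng(0).normal(size=(5, 3)), np.ones(5), 1)


class TestLooQ2:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for trial in range(3):
            X = rng.normal(size=(12, 6))
            y = rng.normal(size=12)
            q2, _ = q.loo_q2(X, y, 2)
            assert q2 == pytest.approx(brute_force_loo(X, y, 2), abs=1e-10)

    def test_perfect_oracle_gives_one(self):
        y = np.arange(8.0)
        press = np.sum((y - y) ** 2)
        tss = np.sum((y - y.mean()) ** 2)
        assert 1.0 - press / tss == 1.0  # definition check

        # a design that contains y exactly: LOO prediction is near-perfect
        X = np.c_[y, np.ones(8)]
        q2, _ = q.loo_q2(X, y, 1)
        assert q2 > 0.99

    def test_mean_predictor_not_positive(self):
        # a predictor that always outputs the training mean: the LOO mean of
        # the remaining n-1 samples makes q2 slightly negative by definition
        rng = np.random.default_rng(5)
        y = rng.normal(size=10)
        press = sum(
            (y[i] - np.delete(y, i).mean()) ** 2 for i in range(len(y))
        )
        q2 = 1.0 - press / np.sum((y - y.mean()) ** 2)
        assert q2 <= 0.0

    def test_masked_columns_do_not_change_q2(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        fm = _field_matrix(values)
        q2_full, _ = q.loo_q2(fm, y, 2)
        extra = _field_matrix(np.c_[values, rng.normal(size=(12, 3))])
        extra.filter_mask[6:] = False
        q2_masked, _ = q.loo_q2(extra, y, 2)
        assert q2_masked == pytest.approx(q2_full, abs=1e-12)

    def test_too_many_components_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 4))
        with pytest.raises(ValueError):
            q.loo_q2(X, np.arange(5.0), 4)


class TestSelectComponents:
    def test_tie_returns_fewest(self, monkeypatch):
        seq = {1: 0.5, 2: 0.7, 3: 0.7, 4: 0.7}
        monkeypatch.setattr(
            "qsar3d.pls.loo_q2", lambda X, y, c: (seq[c], 0.0)
        )
        from qsar3d.pls import select_components

        assert select_components(np.zeros((9, 4)), np.arange(9.0), 4) == 2

    def test_recovers_planted_factor_count(self):
        rng = np.random.default_rng(99)
        T = rng.normal(size=(24, 2))
        P = rng.normal(size=(2, 10))
        X = T @ P
        y = T @ np.array([1.0, -0.7]) + rng.normal(scale=0.02, size=24)
        assert q.select_components(X, y, 5) == 2

    def test_max_one_returns_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3))
        assert q.select_components(X, rng.normal(size=8), 1) == 1


class TestExternalValidate:
    def test_identical_vectors(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        ev = q.external_validate(y, y)
        assert ev.rmsep == 0.0
        assert ev.r2_pred == pytest.approx(1.0)
        assert ev.k_slope == pytest.approx(1.0)
        assert ev.k_prime_slope == pytest.approx(1.0)
        assert ev.gt_ratio == pytest.approx(0.0, abs=1e-12)

    def test_published_test_split_statistics(self):
        ev = q.published_split_statistics("comfa", "test")
        assert ev.rmsep == pytest.approx(0.226, abs=5e-4)
        assert ev.r2_pred == pytest.approx(0.891, abs=2e-3)
        assert ev.passes_golbraikh_tropsha

    def test_published_validation_split_statistics(self):
        ev = q.published_split_statistics("comfa", "validation")
        assert ev.r2_pred == pytest.approx(0.790, abs=2e-3)

    def test_affine_rescaling_separates_r2_from_slope(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=10)
        yhat = y + rng.normal(scale=0.1, size=10)
        base = q.external_validate(yhat, y)
        scaled = q.external_validate(2.0 * yhat + 1.0, y)
        assert scaled.r2_pred == pytest.approx(base.r2_pred, abs=1e-12)
        assert scaled.k_slope != pytest.approx(base.k_slope, abs=1e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            q.external_validate(np.ones(4), np.arange(4.0))


class TestSummaryStatistics:
    def test_f_convention_reproduces_published_pairing(self):
        # r2 = 0.856 with n = 26 training compounds and 3 latent variables
        r2, n, c = 0.856, 26, 3
        f = (r2 / c) / ((1 - r2) / (n - c - 1))
        assert f == pytest.approx(43.6, abs=0.5)

    def test_perfect_fit_guarded(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        beta = np.array([1.0, -2.0, 0.5])
        y = X @ beta
        model = q.fit_pls(X, y, 3)
        stats = q.summary_statistics(model, X, y)
        assert stats.see == pytest.approx(0.0, abs=1e-7)
        assert stats.f_value > 1e6 or math.isinf(stats.f_value)

    def test_y_scrambling_degrades_fit(self):
        rng = np.random.default_rng(123)
        X = rng.normal(size=(20, 10))
        y = X[:, 0] + 0.2 * rng.normal(size=20)
        model = q.fit_pls(X, y, 3)
        r2_true = q.summary_statistics(model, X, y).r2_ncv
        y_perm = rng.permutation(y)
        model_p = q.fit_pls(X, y_perm, 3)
        r2_perm = q.summary_statistics(model_p, X, y_perm).r2_ncv
        assert r2_perm < r2_true

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 3))
        y = rng.normal(size=4)
        model = q.fit_pls(X, y, 3)
        with pytest.raises(ValueError):
            q.summary_statistics(model, X, y)


class TestFieldFractions:
    def test_single_kind_gets_everything(self):
        rng = np.random.default_rng(11)
        fm = _field_matrix(rng.normal(size=(10, 4)))
        model = q.fit_pls(fm, rng.normal(size=10), 2)
        assert q.field_fractions(model) == {"steric": pytest.approx(1.0)}

    def test_duplicated_kinds_split_evenly(self):
        rng = np.random.default_rng(12)
        block = rng.normal(size=(10, 3))
        fm = _field_matrix(np.c_[block, block],
                           kinds=["steric"] * 3 + ["electrostatic"] * 3)
        model = q.fit_pls(fm, rng.normal(size=10), 2)
        fr = q.field_fractions(model)
        assert fr["steric"] == pytest.approx(0.5, abs=1e-9)
        assert fr["electrostatic"] == pytest.approx(0.5, abs=1e-9)

    def test_fractions_sum_to_one(self, benchmark_results):
        for name, res in benchmark_results.items():
            assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_planted_steric_signal_dominates(self, synthetic_default):
        model = q.fit_pls(synthetic_default.field_matrix,
                          synthetic_default.activities, 3)
        fr = q.field_fractions(model)
        assert fr["steric"] > fr["electrostatic"]


class TestContours:
    def test_all_zero_coefficients_give_empty_sets(self):
        rng = np.random.default_rng(13)
        fm = _field_matrix(rng.normal(size=(8, 3)))
        model = q.fit_pls(fm, rng.normal(size=8), 1)
        model.coefficients = np.zeros_like(model.coefficients)
        out = q.extract_contours(model)
        assert out["steric"].favored_points == []
        assert out["steric"].disfavored_points == []

    def test_single_positive_column_is_whole_favored_set(self):
        values = np.array([[0.0], [1.0], [2.0], [3.0]])
        fm = _field_matrix(values)
        y = np.array([0.0, 1.0, 2.0, 3.0])
        model = q.fit_pls(fm, y, 1)
        out = q.extract_contours(model)
        assert len(out["steric"].favored_points) == 1
        assert out["steric"].favored_points[0][0] == (0, 0, 0)

    def test_favored_and_disfavored_disjoint(self, benchmark_results):
        for res in benchmark_results.values():
            for cs in res.contours.values():
                fav = {p for p, _ in cs.favored_points}
                dis = {p for p, _ in cs.disfavored_points}
                assert not fav & dis

    def test_planted_column_in_favored_set(self, synthetic_default):
        data = synthetic_default
        model = q.fit_pls(data.field_matrix, data.activities, 3)
        contours = q.extract_contours(model)
        favored = {
            (cs.field_kind, p) for cs in contours.values()
            for p, _ in cs.favored_points
        }
        for g in data.planted_indices:
            pt = tuple(int(v) for v in data.field_matrix.point_index[g])
            assert ("steric", pt) in favored
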