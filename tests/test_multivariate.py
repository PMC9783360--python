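import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from tabletability.mechanics import compaction_pressure
from tabletability.multivariate import (
    autoscale,
    build_fusion_design,
    hotelling_ellipse,
    pca,
    pls2_fit,
    q2_crossval,
)


class TestAutoscale:
    def test_column_123_scales_to_sample_units(self):
        # sample (n−1) convention: std of (1,2,3) is exactly 1
        scaled, _ = autoscale(np.array([[1.0], [2.0], [3.0]]))
        assert scaled.ravel() == pytest.approx([-1.0, 0.0, 1.0], abs=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 4)) * 5 + 3
        once, _ = autoscale(x)
        twice, _ = autoscale(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(15, 3)) * 2 + 10
        scaled, scaler = autoscale(x)
        assert np.allclose(scaler.inverse_transform(scaled), x, atol=1e-12)

    def test_zero_variance_column_named(self):
        frame = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            autoscale(frame)


class TestPCA:
    def test_rank_one_matrix_pc1_explains_everything(self):
        u = np.linspace(-1, 1, 10)[:, None]
        v = np.array([[1.0, -2.0, 0.5]])
        res = pca(u @ v, n_components=1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_correlation_eigendecomposition(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 6)) @ rng.normal(size=(6, 6))
        scaled, _ = autoscale(x)
        res = pca(scaled)
        corr = np.corrcoef(x, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        assert np.allclose(
            res.explained_variance_ratio, eig[: len(res.explained_variance_ratio)] / 6,
            atol=1e-10,
        )

    def test_loadings_orthonormal_and_variance_ordered(self, clean_result):
        res = clean_result.pca_properties
        gram = res.loadings.T @ res.loadings
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10)
        evr = res.explained_variance_ratio
        assert all(b <= a + 1e-12 for a, b in zip(evr, evr[1:]))
        assert evr.sum() <= 1.0 + 1e-12

    def test_sign_convention_deterministic_under_row_permutation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 5))
        scaled, _ = autoscale(x)
        res = pca(scaled, n_components=3)
        perm = rng.permutation(30)
        res_perm = pca(scaled[perm], n_components=3)
        assert np.allclose(res.loadings, res_perm.loadings, atol=1e-8)


class TestHotellingEllipse:
    def test_isotropic_scores_give_near_circle(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(2000, 2))
        ell = hotelling_ellipse(scores)
        assert ell.semi_axes[0] / ell.semi_axes[1] < 1.1

    def test_coverage_close_to_nominal(self):
        rng = np.random.default_rng(5)
        scores = rng.multivariate_normal([1.0, -2.0], [[2.0, 0.7], [0.7, 1.0]], 100_000)
        ell = hotelling_ellipse(scores, confidence=0.95)
        # map points into the ellipse frame and count those inside
        c, s = np.cos(ell.angle_rad), np.sin(ell.angle_rad)
        rot = np.array([[c, s], [-s, c]])
        rel = (scores - np.asarray(ell.center)) @ rot.T
        inside = (rel[:, 0] / ell.semi_axes[0]) ** 2 + (
            rel[:, 1] / ell.semi_axes[1]
        ) ** 2 <= 1.0
        assert 0.94 <= inside.mean() <= 0.96

    def test_translation_equivariance(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=(50, 2))
        base = hotelling_ellipse(scores)
        shifted = hotelling_ellipse(scores + np.array([3.0, -1.0]))
        assert shifted.center[0] == pytest.approx(base.center[0] + 3.0, abs=1e-10)
        assert shifted.center[1] == pytest.approx(base.center[1] - 1.0, abs=1e-10)
        assert shifted.semi_axes == pytest.approx(base.semi_axes, rel=1e-10)

    def test_singular_covariance_flagged_degenerate(self):
        line = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)])
        assert hotelling_ellipse(line).degenerate

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            hotelling_ellipse(np.zeros((2, 2)))


class TestFusionDesign:
    def test_dimensions_29_by_5(self, clean_result):
        fusion = clean_result.fusion
        assert fusion.X.shape == (145, 31)
        assert fusion.Y.shape == (145, 2)
        assert (fusion.Y > 0).all().all()

    def test_ts1_composed_from_power_fit_and_pressure(self, clean_result):
        fusion = clean_result.fusion
        cbcs = clean_result.cbcs.set_index(["material_id", "form"])
        mat = clean_result.indices["material_id"].iloc[0]
        d_p, g_p = cbcs.loc[(mat, "powder"), ["d", "g"]]
        p3 = compaction_pressure(3.0, 10.0)
        row = fusion.Y.loc[f"{mat}@{p3:.2f}MPa"]
        assert row["TS1_MPa"] == pytest.approx(d_p * p3**g_p, rel=1e-12)

    def test_removing_one_material_removes_five_rows(self, clean_library, clean_result):
        _, materials, _, _ = clean_library
        prop_cols = [c for c in materials.columns
                     if c not in ("material_id", "form", "material_class")]
        powder = materials[materials["form"] == "powder"]
        drop_id = powder["material_id"].iloc[0]
        fusion = build_fusion_design(
            powder[powder["material_id"] != drop_id][["material_id"] + prop_cols],
            clean_result.cbcs,
            clean_result.indices,
        )
        assert fusion.X.shape == (140, 31)

    def test_material_missing_power_fit_excluded_with_record(self, clean_library, clean_result):
        _, materials, _, _ = clean_library
        prop_cols = [c for c in materials.columns
                     if c not in ("material_id", "form", "material_class")]
        powder = materials[materials["form"] == "powder"]
        cbcs = clean_result.cbcs.copy()
        victim = cbcs["material_id"].iloc[0]
        cbcs.loc[(cbcs["material_id"] == victim) & (cbcs["form"] == "powder"), "d"] = np.nan
        fusion = build_fusion_design(
            powder[["material_id"] + prop_cols], cbcs, clean_result.indices
        )
        assert victim in fusion.excluded
        assert fusion.X.shape == (140, 31)


def _pls1_oracle(x, y, n_lv):
    """Brute-force single-response NIPALS PLS (independent of pls2_fit)."""
    xr = x.copy()
    yr = y.astype(float).copy()
    ws, ps, qs = [], [], []
    for _ in range(n_lv):
        w = xr.T @ yr
        w /= np.linalg.norm(w)
        t = xr @ w
        p = xr.T @ t / (t @ t)
        q = float(yr @ t / (t @ t))
        xr = xr - np.outer(t, p)
        yr = yr - q * t
        ws.append(w), ps.append(p), qs.append(q)
    w, p, q = np.column_stack(ws), np.column_stack(ps), np.array(qs)
    return x @ (w @ np.linalg.solve(p.T @ w, q))


class TestPLS2:
    def _design(self, seed=0, n=60, p=8, m=2, noise=0.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, p))
        b = rng.normal(size=(p, m))
        y = x @ b + noise * rng.normal(size=(n, m))
        xs, _ = autoscale(x)
        ys, _ = autoscale(y)
        return xs, ys

    def test_noiseless_linear_map_fully_explained(self):
        xs, ys = self._design()
        fit = pls2_fit(xs, ys, n_lv=8)
        assert fit.r2y_cum[-1] == pytest.approx(1.0, abs=1e-8)

    def test_single_column_y_matches_pls1_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(50, 6))
        y = x @ rng.normal(size=6) + 0.1 * rng.normal(size=50)
        xs, _ = autoscale(x)
        ys, _ = autoscale(y[:, None])
        fit = pls2_fit(xs, ys, n_lv=4)
        oracle_pred = _pls1_oracle(xs, ys.ravel(), 4)
        assert np.allclose(fit.predict(xs).ravel(), oracle_pred, atol=1e-8)

    def test_predictions_match_sklearn_on_two_block_data(self):
        xs, ys = self._design(seed=8, noise=0.3)
        fit = pls2_fit(xs, ys, n_lv=4)
        sk = PLSRegression(n_components=4, scale=False, tol=1e-12, max_iter=10_000).fit(xs, ys)
        assert np.allclose(fit.predict(xs), sk.predict(xs), atol=1e-6)

    def test_successive_scores_orthogonal(self, clean_result):
        scores = clean_result.pls.x_scores
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_r2_sequences_nondecreasing(self, clean_result):
        for seq in (clean_result.pls.r2x_cum, clean_result.pls.r2y_cum):
            assert all(b >= a - 1e-12 for a, b in zip(seq, seq[1:]))

    def test_rank_bound_enforced(self):
        xs, ys = self._design(n=10, p=4)
        with pytest.raises(ValueError):
            pls2_fit(xs, ys, n_lv=5)

    def test_planted_sign_structure_recovered(self):
        # two planted drivers with opposite signs toward both responses
        rng = np.random.default_rng(9)
        x = rng.normal(size=(80, 6))
        y = np.column_stack([
            2.0 * x[:, 0] - 1.5 * x[:, 1] + 0.05 * rng.normal(size=80),
            1.5 * x[:, 0] - 2.0 * x[:, 1] + 0.05 * rng.normal(size=80),
        ])
        xs, _ = autoscale(x)
        ys, _ = autoscale(y)
        fit = pls2_fit(xs, ys, n_lv=4)
        assert fit.r2y_cum[-1] >= 0.95
        coef = fit.coefficients()
        assert (coef[0] > 0).all() and (coef[1] < 0).all()


class TestQ2:
    def test_noiseless_linear_q2_tracks_r2(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(70, 6))
        y = x @ rng.normal(size=(6, 2))
        q2 = q2_crossval(x, y, max_lv=6)
        xs, _ = autoscale(x)
        ys, _ = autoscale(y)
        r2 = pls2_fit(xs, ys, n_lv=6).r2y_cum
        assert q2[-1] == pytest.approx(r2[-1], abs=0.02)

    def test_pure_noise_q2_nonpositive_in_expectation(self):
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(35, 5))
            y = rng.normal(size=(35, 2))
            vals.append(q2_crossval(x, y, max_lv=2)[-1])
        assert np.mean(vals) <= 0.0

    def test_round_robin_assignment_is_deterministic(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(40, 5))
        y = x @ rng.normal(size=(5, 2)) + 0.2 * rng.normal(size=(40, 2))
        assert np.allclose(
            q2_crossval(x, y, max_lv=3), q2_crossval(x, y, max_lv=3), atol=0
        )

    def test_library_q2_below_r2y(self, clean_result):
        summary = clean_result.pls_summary
        assert (summary["Q2_cum"] <= summary["R2Y_cum"] + 0.02).all()

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            q2_crossval(np.zeros((5, 2)), np.zeros((5, 1)), max_lv=1, n_folds=9)
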