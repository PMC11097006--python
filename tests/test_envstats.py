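"""Environmental extraction, descriptive statistics, VIF pruning and PCA."""

import numpy as np
import pandas as pd
import pytest

import ginkgosdm as g
from ginkgosdm.envstats import EnvMatrix, VIF_SENTINEL


def _env(data: dict) -> EnvMatrix:
    return EnvMatrix(values=pd.DataFrame(data))


class TestExtractAtPoints:
    def test_constant_layer_returns_constant(self):
        georef = g.GridGeoref(n_rows=5, n_cols=5, origin_lon=100,
                              origin_lat=35, cell_size=1.0)
        stack = g.ClimateStack(georef=georef,
                               layers={"c": np.full((5, 5), 7.0)})
        occ = g.OccurrenceTable(frame=pd.DataFrame(
            {"id": ["p"], "lon": [102.5], "lat": [32.5]}))
        env = g.extract_at_points(stack, occ)
        assert env.values.loc["p", "c"] == 7.0

    def test_nodata_row_dropped_and_counted(self):
        georef = g.GridGeoref(n_rows=2, n_cols=2, origin_lon=0,
                              origin_lat=2, cell_size=1.0)
        mask = np.array([[True, False], [True, True]])
        stack = g.ClimateStack(georef=georef,
                               layers={"v": np.ones((2, 2))}, mask=mask)
        occ = g.OccurrenceTable(frame=pd.DataFrame(
            {"id": ["ok", "hole"], "lon": [0.5, 1.5], "lat": [1.5, 1.5]}))
        env = g.extract_at_points(stack, occ)
        assert len(env) == 1
        assert env.n_dropped_nodata == 1

    def test_point_outside_extent_names_record(self, small_stack):
        occ = g.OccurrenceTable(frame=pd.DataFrame(
            {"id": ["lost"], "lon": [0.0], "lat": [0.0]}))
        with pytest.raises(ValueError, match="lost"):
            g.extract_at_points(small_stack, occ)


class TestDescriptiveStats:
    def test_reported_precipitation_row(self):
        """cv and 95% CI arithmetic on a mean/sd/n matching the printed
        annual-precipitation row: cv 33.2, CI 1083.7 to 1142.7."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal(604)
        x = (x - x.mean()) / x.std(ddof=1)  # exact zero mean, unit sd
        env = _env({"bio12": 1113.2 + 369.4 * x})
        row = g.descriptive_stats(env).loc["bio12"]
        assert row["mean"] == pytest.approx(1113.2)
        assert row["sd"] == pytest.approx(369.4)
        assert row["cv"] == 33.2
        assert (row["ci95_low"], row["ci95_high"]) == (1083.7, 1142.7)

    def test_constant_column_degenerate_spread(self):
        env = _env({"c": np.full(10, 5.0), "x": np.arange(10.0)})
        row = g.descriptive_stats(env).loc["c"]
        assert row["sd"] == 0.0 and row["cv"] == 0.0
        assert row["ci95_low"] == row["ci95_high"] == 5.0

    def test_zero_mean_cv_undefined(self):
        env = _env({"z": np.array([-1.0, 1.0, -2.0, 2.0]),
                    "x": np.arange(4.0)})
        row = g.descriptive_stats(env).loc["z"]
        assert np.isnan(row["cv"])

    def test_ci_width_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(7)
        widths = []
        for n in (100, 400):
            env = _env({"v": rng.standard_normal(n), "w": rng.standard_normal(n)})
            t = g.descriptive_stats(env, decimals=None)
            widths.append(t.loc["v", "ci95_high"] - t.loc["v", "ci95_low"])
        assert widths[1] < widths[0]
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.25)


def _brute_force_vif(X: np.ndarray, j: int) -> float:
    """Independent oracle: normal-equations regression of column j."""
    y = X[:, j]
    others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
    beta, *_ = np.linalg.lstsq(others, y, rcond=None)
    resid = y - others @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - ss_res / ss_tot
    return 1.0 / (1.0 - r2)


class TestVifStepwise:
    def test_orthogonal_variables_all_unit_vif(self):
        n = 64
        t = np.arange(n)
        # exactly orthogonal columns: sinusoids at distinct frequencies
        env = _env({
            "s1": np.sin(2 * np.pi * t / n), "s2": np.sin(4 * np.pi * t / n),
            "s3": np.sin(6 * np.pi * t / n)})
        report = g.vif_stepwise(env)
        assert report.dropped == []
        np.testing.assert_allclose(report.rounds[0]["vif"], 1.0, atol=1e-8)

    def test_duplicated_column_dropped_first_round(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(50)
        env = _env({"a": a, "a_copy": a.copy(),
                    "b": rng.standard_normal(50)})
        report = g.vif_stepwise(env)
        assert len(report.dropped) == 1
        assert report.dropped[0][0] in ("a", "a_copy")
        assert report.dropped[0][1] == VIF_SENTINEL

    def test_vif_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        x1 = rng.standard_normal(200)
        x2 = rng.standard_normal(200)
        x3 = x1 + x2 + 0.1 * rng.standard_normal(200)
        env = _env({"x1": x1, "x2": x2, "x3": x3})
        X = env.values.to_numpy()
        report = g.vif_stepwise(env, threshold=1e6)
        for j, var in enumerate(["x1", "x2", "x3"]):
            ours = float(report.rounds[0].set_index("variable").loc[var, "vif"])
            assert ours == pytest.approx(_brute_force_vif(X, j), abs=1e-6)

    def test_kept_variables_all_below_threshold(self, study_env):
        report = g.vif_stepwise(study_env, threshold=5.0)
        final = report.rounds[-1]
        assert (final["vif"] < 5.0).all()
        assert set(final["variable"]) == set(report.kept)


class TestPca:
    def test_two_variable_closed_form(self):
        """Correlation rho = 0.6 gives eigenvalues (1.6, 0.4) -> (80%, 20%)."""
        rng = np.random.default_rng(4)
        n = 20000
        z = rng.standard_normal((n, 2))
        rho = 0.6
        x = z[:, 0]
        y = rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1]
        # enforce the exact sample correlation via whitening then recoloring
        w = np.column_stack([x, y])
        w = (w - w.mean(0)) / w.std(0, ddof=1)
        c = np.linalg.cholesky(np.linalg.inv(np.corrcoef(w.T)))
        white = w @ c
        target = np.linalg.cholesky(np.array([[1, rho], [rho, 1]]))
        data = white @ target.T
        result = g.pca(_env({"a": data[:, 0], "b": data[:, 1]}))
        np.testing.assert_allclose(result.eigenvalues, [1.6, 0.4], atol=1e-9)
        np.testing.assert_allclose(result.proportion_of_variance, [80.0, 20.0],
                                   atol=1e-9)

    def test_trace_conservation(self, study_env):
        result = g.pca(study_env)
        assert result.proportion_of_variance.sum() == pytest.approx(100.0)
        assert result.eigenvalues.sum() == pytest.approx(
            len(study_env.variables))

    def test_reconstruction_of_correlation_matrix(self, study_env):
        result = g.pca(study_env)
        L = result.loadings.to_numpy()
        rebuilt = L @ np.diag(result.eigenvalues) @ L.T
        corr = np.corrcoef(study_env.values.to_numpy(), rowvar=False)
        np.testing.assert_allclose(rebuilt, corr, atol=1e-8)

    def test_sign_convention(self, study_env):
        L = g.pca(study_env).loadings.to_numpy()
        for k in range(L.shape[1]):
            col = L[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_matches_sklearn_on_standardized_data(self, study_env):
        sklearn = pytest.importorskip("sklearn.decomposition")
        x = study_env.values.to_numpy()
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        ref = sklearn.PCA().fit(z)
        result = g.pca(study_env)
        np.testing.assert_allclose(result.eigenvalues,
                                   ref.explained_variance_, rtol=1e-8)

    def test_zero_variance_column_named(self):
        env = _env({"flat": np.full(10, 3.0), "x": np.arange(10.0)})
        with pytest.raises(ValueError, match="flat"):
            g.pca(env)
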