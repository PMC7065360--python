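"""Spline smoother DF semantics, logistic fitting, dataset smoothing."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, minimize

import setgrowth as sg
from setgrowth import DomainError, ParameterError, StartValueError
from setgrowth.smoothing import (
    effective_df,
    lambda_for_df,
    penalty_matrix,
    smoother_matrix,
)

from conftest import make_ds

T35 = np.arange(17.0, 52.0)


def _ols_line(t, y):
    X = np.column_stack([np.ones_like(t), t])
    return X @ np.linalg.lstsq(X, y, rcond=None)[0]


class TestSplineCore:
    def test_df_n_interpolates(self):
        rng = np.random.default_rng(1)
        y = rng.normal(50, 10, T35.size)
        fit = sg.spline_smooth(T35, y, df=T35.size)
        np.testing.assert_allclose(fit.fitted, y, atol=1e-8)

    def test_df_2_is_ols_line(self):
        rng = np.random.default_rng(2)
        y = rng.normal(50, 10, T35.size)
        fit = sg.spline_smooth(T35, y, df=2.0)
        np.testing.assert_allclose(fit.fitted, _ols_line(T35, y), atol=1e-8)

    @pytest.mark.parametrize("df", [2.5, 4.0, 5.0, 6.0, 12.0, 20.0])
    def test_achieved_df_matches_request(self, df):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, T35.size)
        fit = sg.spline_smooth(T35, y, df=df)
        assert abs(fit.achieved_df - df) < 1e-6

    @pytest.mark.parametrize("df", [2.0, 3.7, 6.0, 20.0, 35.0])
    def test_linear_data_reproduced_exactly(self, df):
        y = 3.0 + 0.5 * T35
        fit = sg.spline_smooth(T35, y, df=df)
        np.testing.assert_allclose(fit.fitted, y, atol=1e-10)

    def test_df_out_of_range_rejected(self):
        y = np.ones(5)
        t = np.arange(5.0)
        for df in (1.5, 6.0):
            with pytest.raises(ParameterError):
                sg.spline_smooth(t, y, df=df)

    def test_trace_decreasing_in_lambda_with_correct_limits(self):
        t = np.array([0.0, 1.0, 2.5, 3.0, 5.0, 7.0, 8.0])
        lams = 10.0 ** np.linspace(-6, 8, 30)
        traces = [effective_df(t, lam) for lam in lams]
        assert all(a > b for a, b in zip(traces, traces[1:]))
        assert effective_df(t, 1e-12) == pytest.approx(t.size, abs=1e-6)
        # approaches the straight-line limit 2 (exact df=2 uses a dedicated
        # OLS branch; the dense solve loses accuracy beyond lambda ~ 1e12)
        assert effective_df(t, 1e12) == pytest.approx(2.0, abs=5e-4)

    def test_smoother_symmetric_and_rss_monotone_in_df(self):
        rng = np.random.default_rng(4)
        t = np.sort(rng.uniform(0, 30, 12))
        y = rng.normal(0, 1, 12)
        lam = lambda_for_df(t, 5.0)
        S = smoother_matrix(t, lam)
        np.testing.assert_allclose(S, S.T, atol=1e-10)
        rss = [
            float(np.sum((y - sg.spline_smooth(t, y, df).fitted) ** 2))
            for df in (3.0, 5.0, 8.0, 11.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(rss, rss[1:]))

    def test_matches_independent_numeric_optimizer(self):
        """Direct minimization of RSS + lambda * int f''^2 (quadrature over
        the natural-interpolant representation) agrees with the linear
        smoother solution."""
        rng = np.random.default_rng(5)
        t = np.array([0.0, 1.0, 2.0, 3.5, 5.0, 6.0, 8.0])
        y = rng.normal(0, 1, t.size)
        df = 4.0
        lam = lambda_for_df(t, df)
        fitted = sg.spline_smooth(t, y, df).fitted

        def objective(g):
            cs = CubicSpline(t, g, bc_type="natural")
            pen = sum(
                quad(lambda x: cs(x, 2) ** 2, a, b, limit=100)[0]
                for a, b in zip(t[:-1], t[1:])
            )
            return float(np.sum((y - g) ** 2) + lam * pen)

        sol = minimize(objective, y, method="BFGS", options={"gtol": 1e-12})
        np.testing.assert_allclose(fitted, sol.x, atol=5e-6)

    def test_penalty_annihilates_linear_sequences(self):
        t = np.array([1.0, 2.0, 4.0, 7.0, 8.0])
        K = penalty_matrix(t)
        np.testing.assert_allclose(K @ np.ones(5), 0.0, atol=1e-12)
        np.testing.assert_allclose(K @ t, 0.0, atol=1e-11)


class TestLogSmoothing:
    def test_constant_preserved(self):
        fit = sg.log_spline_smooth(T35, np.full(T35.size, 7.0), df=4.0)
        np.testing.assert_allclose(fit.fitted, 7.0, atol=1e-10)

    def test_exact_exponential_with_df2(self):
        y = 2.0 * np.exp(0.08 * T35)
        fit = sg.log_spline_smooth(T35, y, df=2.0)
        np.testing.assert_allclose(fit.fitted, y, rtol=1e-8)

    def test_positive_output_and_domain_error(self):
        rng = np.random.default_rng(6)
        y = np.exp(rng.normal(0, 2, T35.size))
        fit = sg.log_spline_smooth(T35, y, df=5.0)
        assert np.all(fit.fitted > 0)
        with pytest.raises(DomainError):
            sg.log_spline_smooth(T35, np.append(y[:-1], 0.0), df=5.0)

    def test_direct_smoothing_underestimates_early_growth_more(self, tomato):
        """On trajectories spanning two orders of magnitude, direct low-DF
        smoothing biases the first days downward relative to log smoothing."""
        ds, _ = tomato
        sub = ds.subject_frame("cart01")
        t = sub["DAP"].to_numpy(float)
        y = sub["PSA"].to_numpy(float)
        direct = sg.spline_smooth(t, y, df=4.0).fitted
        logf = sg.log_spline_smooth(t, y, df=6.0).fitted
        early = slice(0, 5)
        dev_direct = np.mean(y[early] - direct[early])
        dev_log = np.mean(y[early] - logf[early])
        assert dev_direct > dev_log  # direct smooth sits further below data


class TestLogistic:
    def test_noiseless_recovery(self):
        y = 100.0 / (1.0 + np.exp(-(T35 - 30.0) / 4.0))
        fit = sg.fit_logistic(T35, y)
        assert fit.converged
        np.testing.assert_allclose(
            [fit.phi1, fit.phi2, fit.phi3], [100.0, 30.0, 4.0], rtol=1e-6
        )

    def test_half_to_three_quarter_time_is_phi3_ln3(self):
        y = 80.0 / (1.0 + np.exp(-(T35 - 32.0) / 5.0)) * (
            1.0 + 0.01 * np.sin(T35)
        )
        fit = sg.fit_logistic(T35, y)
        t_half = brentq(lambda t: fit.predict(t) - fit.phi1 / 2.0, 0.0, 100.0)
        t_3q = brentq(lambda t: fit.predict(t) - 0.75 * fit.phi1, 0.0, 100.0)
        assert t_3q - t_half == pytest.approx(fit.phi3 * np.log(3.0), abs=1e-8)

    def test_degenerate_data_raise_start_value_error(self):
        with pytest.raises(StartValueError):
            sg.fit_logistic(T35, np.full(T35.size, 3.0))


class TestSmoothDataset:
    def test_achieved_df_per_subject(self, smoothed_log6):
        assert len(smoothed_log6.fits) == 32
        for fit in smoothed_log6.fits.values():
            assert abs(fit.achieved_df - 6.0) < 1e-6

    def test_adds_smoothed_columns_and_grs(self, smoothed_log6):
        cols = smoothed_log6.dataset.data.columns
        for c in ("sPSA", "sPSA.AGR", "sPSA.RGR"):
            assert c in cols

    def test_short_subject_reported_not_fatal(self):
        rows = [
            {"subject": "ok", "DAP": t, "PSA": 2.0 + t} for t in range(1, 9)
        ] + [{"subject": "tiny", "DAP": t, "PSA": 1.0 + t} for t in (1, 2, 3)]
        ds = make_ds(rows)
        res = sg.smooth_dataset(ds, "PSA", sg.SmoothingScheme(scale="direct", df=5.0))
        assert "ok" in res.fits and "tiny" not in res.fits
        assert list(res.failures["subject"]) == ["tiny"]

    def test_imputed_value_between_monotone_neighbours(self):
        t_all = np.arange(17, 40)
        rows = [
            {"subject": "c1", "DAP": int(t), "PSA": float(np.exp(0.1 * t))}
            for t in t_all
            if t != 30
        ] + [
            {"subject": "c2", "DAP": int(t), "PSA": float(np.exp(0.1 * t) * 1.1)}
            for t in t_all
        ]
        ds = make_ds(rows)
        res = sg.smooth_dataset(
            ds, "PSA", sg.SmoothingScheme(scale="log", df=5.0), impute_missing=True
        )
        d = res.dataset.data
        sub = d[d["subject"] == "c1"].set_index("DAP")["sPSA"]
        assert 30 in sub.index
        lo, hi = sorted((sub.loc[29], sub.loc[31]))
        assert lo <= sub.loc[30] <= hi

    def test_logistic_engine_rgr_strictly_decreasing(self):
        y = 120.0 / (1.0 + np.exp(-(T35 - 33.0) / 4.0))
        ds = make_ds(
            [
                {"subject": "c1", "DAP": int(t), "PSA": float(v)}
                for t, v in zip(T35, y)
            ]
        )
        res = sg.smooth_dataset(ds, "PSA", sg.SmoothingScheme(engine="logistic"))
        rgr = res.dataset.data["sPSA.RGR"].dropna().to_numpy()
        assert np.all(np.diff(rgr) < 0)


class TestSegmentedSmoothing:
    def test_no_breakpoints_identical_to_plain_smooth(self, tomato_gr):
        scheme = sg.SmoothingScheme(scale="log", df=5.0)
        plain = sg.smooth_dataset(tomato_gr, "PSA", scheme)
        seg = sg.segmented_smooth(tomato_gr, "PSA", [], scheme)
        np.testing.assert_allclose(
            seg.dataset.data["sPSA"].to_numpy(),
            plain.dataset.data["sPSA"].to_numpy(),
        )

    def test_breakpoint_outside_range_rejected(self, tomato_gr):
        with pytest.raises(ParameterError, match="outside"):
            sg.segmented_smooth(
                tomato_gr, "PSA", [60], sg.SmoothingScheme(df=4.0)
            )

    def test_segmentation_helps_on_abrupt_agr_change(self, tomato):
        """Splitting at the watering-interruption onset reduces the total
        absolute deviation relative to one global low-DF smooth."""
        ds, _ = tomato
        scheme = sg.SmoothingScheme(scale="log", df=4.0)
        plain = sg.smooth_dataset(ds, "PSA", scheme)
        seg = sg.segmented_smooth(ds, "PSA", [39], scheme)

        def total_abs_dev(res):
            d = res.dataset.data
            return float((d["PSA"] - d["sPSA"]).abs().sum())

        assert total_abs_dev(seg) < total_abs_dev(plain)
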