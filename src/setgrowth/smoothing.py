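"""Per-subject smoothing of growth trajectories.

Three engines are provided:

* natural cubic smoothing splines with a *user-specified effective degrees
  of freedom* (EDF), fitted either to the raw trait ("direct" scale) or to
  its natural logarithm with exponential backtransform ("log" scale);
* a three-parameter logistic curve ``y(t) = phi1 / (1 + exp(-(t-phi2)/phi3))``
  fitted by nonlinear least squares, where ``phi1`` is the upper asymptote,
  ``phi2`` the time at which half the asymptote is reached and ``phi3`` a
  scale parameter (the elapsed time from half to three-quarters of the
  asymptote is exactly ``phi3 * ln 3``);
* segmented smoothing: the time axis is split at breakpoints and each
  segment smoothed independently (useful around abrupt growth-rate changes
  such as a watering interruption).

The smoothing spline minimizes ``sum (y_i - f(t_i))^2 + lambda * int f''^2``
over natural cubic splines with knots at the observed times (Green-Silverman
formulation). The penalty ``lambda`` is not exposed directly: it is solved
for so that the trace of the linear smoother matrix ``S_lambda`` equals the
requested DF. DF = 2 fits the least-squares straight line; DF = n
interpolates the data. High-throughput phenotyping practice keeps DF small
(4-6): transient day-to-day deviations demand heavy smoothing, and
automatic selectors (CV, REML) systematically under-smooth such data.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, least_squares

from ._errors import (
    DomainError,
    IntegrityError,
    ParameterError,
    StartValueError,
)
from .longdata import LongitudinalDataset, derive_continuous_gr

__all__ = [
    "SmoothingScheme",
    "SmoothFit",
    "LogisticFit",
    "SmoothResult",
    "spline_smooth",
    "log_spline_smooth",
    "fit_logistic",
    "smooth_dataset",
    "segmented_smooth",
    "penalty_matrix",
    "smoother_matrix",
    "effective_df",
    "lambda_for_df",
]

#: tolerance on |trace(S_lambda) - df| for the penalty root-finder
DF_TOL = 1e-6
#: requested df closer than this to the boundary 2 or n is treated exactly
_BOUNDARY_EPS = 1e-9


# ---------------------------------------------------------------------------
# natural cubic smoothing spline core (Green-Silverman band formulation)
# ---------------------------------------------------------------------------

def _check_times(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 3:
        raise ParameterError("need at least 3 observation times")
    if np.any(np.diff(t) <= 0):
        if np.any(np.diff(np.sort(t)) == 0):
            raise IntegrityError("duplicate observation times")
        raise ParameterError("times must be strictly increasing")
    return t


def penalty_matrix(times: Sequence[float]) -> np.ndarray:
    """Roughness penalty K with ``f' K f = int f''(t)^2 dt`` for a natural
    cubic spline f with knots at ``times``, f given by its knot values.

    Built from the tridiagonal band matrices Q (n x (n-2)) and R
    ((n-2) x (n-2)) of the Green-Silverman formulation: K = Q R^-1 Q'.
    K annihilates constant and linear sequences, so the smoother preserves
    straight lines exactly for every lambda.
    """
    t = _check_times(times)
    n = t.size
    h = np.diff(t)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        Q[j - 1, j - 1] = 1.0 / h[j - 1]
        Q[j, j - 1] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, j - 1] = 1.0 / h[j]
        R[j - 1, j - 1] = (h[j - 1] + h[j]) / 3.0
        if j < n - 2:
            R[j - 1, j] = R[j, j - 1] = h[j] / 6.0
    return Q @ np.linalg.solve(R, Q.T)


def smoother_matrix(times: Sequence[float], lam: float) -> np.ndarray:
    """Linear smoother ``S = (I + lambda K)^-1``; fitted values are S @ y."""
    K = penalty_matrix(times)
    n = K.shape[0]
    return np.linalg.solve(np.eye(n) + lam * K, np.eye(n))


def effective_df(times: Sequence[float], lam: float) -> float:
    """trace(S_lambda): continuous, strictly decreasing in lambda, with
    limits n (lambda -> 0) and 2 (lambda -> infinity)."""
    return float(np.trace(smoother_matrix(times, lam)))


def _line_hat(t: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(t), t])
    return X @ np.linalg.solve(X.T @ X, X.T)


def lambda_for_df(times: Sequence[float], df: float, tol: float = DF_TOL) -> float:
    """Solve trace(S_lambda) = df for lambda by bracketed root-finding on
    log10(lambda). Requires 2 < df < n strictly."""
    t = _check_times(times)
    n = t.size
    if not (2.0 < df < n):
        raise ParameterError(f"df={df} outside the open interval (2, {n})")
    K = penalty_matrix(t)
    eye = np.eye(n)

    def excess(u: float) -> float:
        return float(np.trace(np.linalg.solve(eye + 10.0**u * K, eye))) - df

    # bracket: scale lambda by the cube of the time range so the initial
    # window is grid-independent
    u0 = 3.0 * np.log10(t[-1] - t[0]) - np.log10(n)
    lo, hi = u0 - 6.0, u0 + 6.0
    f_lo, f_hi = excess(lo), excess(hi)
    for _ in range(60):
        if f_lo > 0 and f_hi < 0:
            break
        if f_lo <= 0:
            lo -= 3.0
            f_lo = excess(lo)
        if f_hi >= 0:
            hi += 3.0
            f_hi = excess(hi)
    else:  # pragma: no cover - defensive
        raise ParameterError(f"could not bracket lambda for df={df}")
    u = brentq(excess, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    lam = 10.0**u
    if abs(excess(u)) > tol:  # pragma: no cover - brentq converges far tighter
        raise ParameterError(f"df root-finder failed: |trace-df|={abs(excess(u))}")
    return lam


@functools.lru_cache(maxsize=256)
def _cached_smoother(t_key: tuple, df: float) -> tuple[float, np.ndarray]:
    """(lambda, S) for a time grid and df. trace(S) depends only on the grid
    and lambda, never on y, so the root-find is shared across subjects."""
    t = np.array(t_key)
    n = t.size
    if df >= n - _BOUNDARY_EPS:
        S = np.eye(n)
        lam = 0.0
    elif df <= 2.0 + _BOUNDARY_EPS:
        S = _line_hat(t)
        lam = np.inf
    else:
        lam = lambda_for_df(t, df)
        S = smoother_matrix(t, lam)
    S.setflags(write=False)
    return lam, S


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoothingScheme:
    """Configuration of one smoothing scheme.

    engine: "spline" or "logistic"; scale: "direct" or "log" (spline only;
    the logistic is always fitted on the direct scale); df: effective
    degrees of freedom of the spline smoother (real-valued, 2 <= df <= n);
    breakpoints: optional DAPs at which to split for segmented smoothing.
    """

    engine: str = "spline"
    scale: str = "log"
    df: float = 6.0
    breakpoints: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.engine not in ("spline", "logistic"):
            raise ParameterError(f"unknown engine {self.engine!r}")
        if self.scale not in ("direct", "log"):
            raise ParameterError(f"unknown scale {self.scale!r}")
        if self.breakpoints is not None:
            bp = tuple(self.breakpoints)
            if any(b >= c for b, c in zip(bp, bp[1:])):
                raise ParameterError("breakpoints must be strictly increasing")
            object.__setattr__(self, "breakpoints", bp)

    @property
    def label(self) -> str:
        if self.engine == "logistic":
            return "logistic"
        df = int(self.df) if float(self.df).is_integer() else self.df
        return f"{self.scale}-{df}"


@dataclass
class SmoothFit:
    """A fitted smooth trajectory for one subject.

    ``fitted`` is on the trait scale (backtransformed if scale="log");
    ``achieved_df`` is trace(S_lambda) (or the logistic parameter count).
    ``predict`` evaluates the underlying curve at arbitrary times: for the
    spline engine this is the natural cubic interpolant of the fitted knot
    values (the exact representation of the smoothing spline), evaluated on
    the fitting scale and backtransformed.
    """

    subject_id: object
    times: np.ndarray
    fitted: np.ndarray
    lam: float
    achieved_df: float
    scheme: SmoothingScheme
    _predict_core: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)

    def predict(self, new_times) -> np.ndarray:
        new_times = np.asarray(new_times, dtype=float)
        return self._predict_core(new_times)


@dataclass
class LogisticFit:
    """Three-parameter logistic fit: phi1 upper asymptote (trait units),
    phi2 time of half-asymptote (DAP), phi3 scale (days)."""

    phi1: float
    phi2: float
    phi3: float
    converged: bool
    residual_ss: float

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.phi1 / (1.0 + np.exp(-(t - self.phi2) / self.phi3))


@dataclass
class SmoothResult:
    """Output of :func:`smooth_dataset` / :func:`segmented_smooth`.

    fits: per-subject SmoothFit; dataset: the input augmented with the
    smoothed trait ``s{trait}`` and its continuous GRs ``s{trait}.AGR`` and
    ``s{trait}.RGR``; failures: per-subject failure/warning report
    (columns subject, stage, message).
    """

    fits: dict
    dataset: LongitudinalDataset
    failures: pd.DataFrame
    trait: str
    scheme: SmoothingScheme

    @property
    def smoothed_column(self) -> str:
        return f"s{self.trait}"


# ---------------------------------------------------------------------------
# single-trajectory smoothers
# ---------------------------------------------------------------------------

def spline_smooth(times, values, df: float) -> SmoothFit:
    """Natural cubic smoothing spline with trace(S_lambda) = df.

    df = 2 reproduces the OLS straight line; df = n interpolates the data;
    linear data are reproduced exactly for every df (the penalty annihilates
    linear trends).
    """
    t = _check_times(times)
    y = np.asarray(values, dtype=float)
    if y.shape != t.shape:
        raise ParameterError("times and values must have equal length")
    n = t.size
    if not (2.0 - _BOUNDARY_EPS <= df <= n + _BOUNDARY_EPS):
        raise ParameterError(f"df={df} outside [2, {n}]")
    lam, S = _cached_smoother(tuple(t), float(df))
    fitted = S @ y
    achieved = float(np.trace(S))
    cs = CubicSpline(t, fitted, bc_type="natural")
    return SmoothFit(
        subject_id=None,
        times=t,
        fitted=fitted,
        lam=lam,
        achieved_df=achieved,
        scheme=SmoothingScheme(engine="spline", scale="direct", df=df),
        _predict_core=lambda x: cs(x),
    )


def log_spline_smooth(times, values, df: float) -> SmoothFit:
    """Spline-smooth ln(values) and backtransform: exp(spline(ln y)).

    Positive data yield positive fitted values by construction; the heavy
    smoothing penalty acts evenly across trajectories spanning orders of
    magnitude, which is why the log scale is usually preferred for early
    growth."""
    y = np.asarray(values, dtype=float)
    if np.any(y <= 0):
        raise DomainError(
            f"log smoothing requires positive values; min={np.nanmin(y)}"
        )
    inner = spline_smooth(times, np.log(y), df)
    core = inner._predict_core
    fit = SmoothFit(
        subject_id=None,
        times=inner.times,
        fitted=np.exp(inner.fitted),
        lam=inner.lam,
        achieved_df=inner.achieved_df,
        scheme=SmoothingScheme(engine="spline", scale="log", df=df),
        _predict_core=lambda x: np.exp(core(x)),
    )
    return fit


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """First linearly interpolated upward crossing of ``level``."""
    for i in range(y.size - 1):
        y0, y1 = y[i], y[i + 1]
        if y0 < level <= y1:
            return t[i] + (level - y0) / (y1 - y0) * (t[i + 1] - t[i])
    raise StartValueError(
        f"no upward crossing of {level:g}: data too flat/degenerate for a "
        "logistic self-start"
    )


def fit_logistic(times, values, max_nfev: int = 500) -> LogisticFit:
    """Nonlinear least squares for the three-parameter logistic.

    Self-start: phi1 = 1.05 * max(y); phi2 = interpolated time at which y
    crosses max(y)/2; phi3 = (t_{3/4} - t_{1/2}) / ln 3 from the interpolated
    quantile-crossing times. Non-convergence is reported via
    ``converged=False`` rather than raised; genuinely degenerate (flat)
    data raise :class:`StartValueError`.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ParameterError("logistic fit needs at least 4 points")
    if np.any(y <= 0):
        raise DomainError("logistic fit requires positive values")
    ymax = float(np.max(y))
    if np.ptp(y) == 0:
        raise StartValueError("constant data: logistic self-start undefined")
    p1 = 1.05 * ymax
    t_half = _interp_crossing(t, y, ymax / 2.0)
    t_threeq = _interp_crossing(t, y, 0.75 * ymax)
    p3 = (t_threeq - t_half) / np.log(3.0)
    if not np.isfinite(p3) or p3 <= 0:
        raise StartValueError("quantile-crossing self-start gave phi3 <= 0")

    def resid(p):
        return p[0] / (1.0 + np.exp(-(t - p[1]) / p[2])) - y

    sol = least_squares(
        resid,
        x0=[p1, t_half, p3],
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=max_nfev,
    )
    phi1, phi2, phi3 = sol.x
    converged = bool(sol.status > 0 and phi1 > 0 and phi3 > 0)
    return LogisticFit(
        phi1=float(phi1),
        phi2=float(phi2),
        phi3=float(phi3),
        converged=converged,
        residual_ss=float(2.0 * sol.cost),
    )


# ---------------------------------------------------------------------------
# dataset-level smoothing
# ---------------------------------------------------------------------------

def _fit_subject(t, y, scheme: SmoothingScheme, subject_id):
    """One subject, one segment: returns (SmoothFit, warning or None)."""
    if scheme.engine == "logistic":
        lf = fit_logistic(t, y)
        warn = None if lf.converged else "logistic fit did not converge"
        fit = SmoothFit(
            subject_id=subject_id,
            times=np.asarray(t, float),
            fitted=lf.predict(t),
            lam=np.nan,
            achieved_df=3.0,
            scheme=scheme,
            _predict_core=lf.predict,
        )
        fit.logistic = lf
        return fit, warn
    if scheme.scale == "log":
        fit = log_spline_smooth(t, y, scheme.df)
    else:
        fit = spline_smooth(t, y, scheme.df)
    fit.subject_id = subject_id
    fit.scheme = scheme
    return fit, None


def smooth_dataset(
    ds: LongitudinalDataset,
    trait: str,
    scheme: SmoothingScheme | None = None,
    impute_missing: bool = False,
) -> SmoothResult:
    """Smooth every subject's ``trait`` trajectory independently.

    Each subject is smoothed on *all* of its observed data (restricting to a
    subinterval invites boundary bias). Subjects with too few points, or
    other per-subject failures, are collected in the failure report rather
    than aborting the run. With ``impute_missing`` the fitted curve is also
    evaluated at the union grid of all observed times, so missing days get
    imputed smoothed values.

    The returned dataset gains columns ``s{trait}``, ``s{trait}.AGR`` and
    ``s{trait}.RGR`` (continuous GRs by differencing the fitted values).
    """
    scheme = scheme or SmoothingScheme()
    if trait not in ds.data.columns:
        raise ParameterError(f"trait {trait!r} not in dataset")
    scol = f"s{trait}"
    df_out = ds.data.copy()
    df_out[scol] = np.nan
    union_times = ds.times
    fits: dict = {}
    failures: list[dict] = []
    extra_rows: list[pd.DataFrame] = []

    for sid, sub in ds.data.groupby(ds.subject, sort=False):
        obs = sub[sub[trait].notna()]
        t = obs[ds.time].to_numpy(dtype=float)
        y = obs[trait].to_numpy(dtype=float)
        need = max(3, int(np.ceil(scheme.df)) if scheme.engine == "spline" else 4)
        if t.size < need:
            failures.append(
                {"subject": sid, "stage": "smooth",
                 "message": f"only {t.size} observations (< {need})"}
            )
            continue
        try:
            fit, warn = _fit_subject(t, y, scheme, sid)
        except (DomainError, StartValueError, ParameterError) as exc:
            failures.append({"subject": sid, "stage": "smooth", "message": str(exc)})
            continue
        if warn:
            failures.append({"subject": sid, "stage": "smooth", "message": warn})
        fits[sid] = fit

        df_out.loc[sub.index, scol] = fit.predict(
            sub[ds.time].to_numpy(dtype=float)
        )
        if impute_missing:
            have = set(sub[ds.time])
            miss = [tt for tt in union_times if tt not in have]
            if miss:
                newrows = pd.DataFrame({ds.subject: sid, ds.time: miss})
                meta = sub.iloc[0]
                carry = ([ds.block] if ds.block else []) + list(ds.factors)
                for c in carry:
                    newrows[c] = meta[c]
                newrows[scol] = fit.predict(np.asarray(miss, dtype=float))
                extra_rows.append(newrows)

    if extra_rows:
        df_out = pd.concat([df_out] + extra_rows, ignore_index=True)
    out_ds = ds.with_data(df_out, traits=tuple(dict.fromkeys(ds.traits + (scol,))))
    out_ds = derive_continuous_gr(out_ds, scol, on_nonpositive="missing")
    fail_df = pd.DataFrame(failures, columns=["subject", "stage", "message"])
    return SmoothResult(
        fits=fits, dataset=out_ds, failures=fail_df, trait=trait, scheme=scheme
    )


class _SegmentedPredictor:
    """Piecewise predictor; a shared breakpoint belongs to the left segment."""

    def __init__(self, fits: list[SmoothFit], breakpoints: Sequence[float]):
        self.fits = fits
        self.breakpoints = np.asarray(breakpoints, dtype=float)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        idx = np.searchsorted(self.breakpoints, x, side="left")
        out = np.empty_like(x)
        for k, fit in enumerate(self.fits):
            m = idx == k
            if m.any():
                out[m] = fit.predict(x[m])
        return out


def segmented_smooth(
    ds: LongitudinalDataset,
    trait: str,
    breakpoints: Sequence[int],
    scheme: SmoothingScheme | None = None,
    impute_missing: bool = False,
) -> SmoothResult:
    """Split each trajectory at ``breakpoints`` and smooth the segments
    independently with ``scheme``.

    A breakpoint time is included in both adjacent segments; the fitted
    value *at* the breakpoint is taken from the earlier segment (continuity
    of the combined curve is not enforced). GRs are derived across the
    concatenated fitted series. With no breakpoints this is exactly
    :func:`smooth_dataset`.
    """
    scheme = scheme or SmoothingScheme()
    breakpoints = sorted(int(b) for b in (breakpoints or []))
    if not breakpoints:
        return smooth_dataset(ds, trait, scheme, impute_missing=impute_missing)
    tmin, tmax = ds.times.min(), ds.times.max()
    for b in breakpoints:
        if not (tmin < b < tmax):
            raise ParameterError(
                f"breakpoint {b} outside the observed time range ({tmin}, {tmax})"
            )
    if any(b2 <= b1 for b1, b2 in zip(breakpoints, breakpoints[1:])):
        raise ParameterError("breakpoints must be strictly increasing")

    scol = f"s{trait}"
    df_out = ds.data.copy()
    df_out[scol] = np.nan
    fits: dict = {}
    failures: list[dict] = []
    edges = [-np.inf] + breakpoints + [np.inf]

    for sid, sub in ds.data.groupby(ds.subject, sort=False):
        obs = sub[sub[trait].notna()]
        t = obs[ds.time].to_numpy(dtype=float)
        y = obs[trait].to_numpy(dtype=float)
        seg_fits: list[SmoothFit] = []
        failed = None
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (t >= lo) & (t <= hi)  # breakpoint shared by both segments
            need = max(3, int(np.ceil(scheme.df)) if scheme.engine == "spline" else 4)
            if m.sum() < need:
                failed = f"segment ({lo}, {hi}] has only {int(m.sum())} points (< {need})"
                break
            try:
                fit, warn = _fit_subject(t[m], y[m], scheme, sid)
            except (DomainError, StartValueError, ParameterError) as exc:
                failed = str(exc)
                break
            if warn:
                failures.append({"subject": sid, "stage": "smooth", "message": warn})
            seg_fits.append(fit)
        if failed is not None:
            failures.append({"subject": sid, "stage": "segmented", "message": failed})
            continue
        predictor = _SegmentedPredictor(seg_fits, breakpoints)
        all_t = sub[ds.time].to_numpy(dtype=float)
        combined = SmoothFit(
            subject_id=sid,
            times=t,
            fitted=predictor(t),
            lam=np.nan,
            achieved_df=float(sum(f.achieved_df for f in seg_fits)),
            scheme=SmoothingScheme(
                engine=scheme.engine, scale=scheme.scale, df=scheme.df,
                breakpoints=tuple(breakpoints),
            ),
            _predict_core=predictor,
        )
        combined.segments = seg_fits
        fits[sid] = combined
        df_out.loc[sub.index, scol] = predictor(all_t)

    out_ds = ds.with_data(df_out, traits=tuple(dict.fromkeys(ds.traits + (scol,))))
    out_ds = derive_continuous_gr(out_ds, scol, on_nonpositive="missing")
    fail_df = pd.DataFrame(failures, columns=["subject", "stage", "message"])
    return SmoothResult(
        fits=fits, dataset=out_ds, failures=fail_df, trait=trait,
        scheme=SmoothingScheme(
            engine=scheme.engine, scale=scheme.scale, df=scheme.df,
            breakpoints=tuple(breakpoints),
        ),
    )
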