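"""Per-trait designed-experiment inference.

Each extracted trait is analysed with the fixed-effects linear model of a
randomized complete-block design,

    y = mu + Block + Zn + AMF + Zn:AMF + e,      e ~ N(0, sigma^2 I),

fitted by ordinary least squares (unbalanced data, e.g. after outlier
removal, are handled by the same normal equations). Inference:

* Wald F tests per term, marginality-respecting (Type II): each main
  effect is adjusted for the block and the other main effects, the
  interaction for all main effects. On a balanced complete design these
  coincide with the classical ANOVA mean-square ratios. The denominator df
  is the residual df — for a fixed-effects-only iid-error model the
  Kenward-Roger denominator df reduces exactly to this.
* Cell predictions for the treatment combinations as estimable functions
  averaging over blocks, with standard errors, the SED for every pair, and
  LSD(alpha) = t_{1-alpha/2, df_resid} * SED. On balanced data all SEDs are
  equal and the LSD is a single number; when they differ the summary LSD
  uses the mean SED (matching the single-ribbon plotting convention) and
  the exact pairwise matrix is also returned.
* Residual diagnostics as tables sufficient to render residual-vs-fitted
  and normal-probability plots (the assessment is visual, by design).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from ._errors import EstimabilityError, ParameterError, SchemaError
from .traits import TraitTable

__all__ = [
    "ModelSpec",
    "AnalysisResult",
    "Predictions",
    "fit_rcbd",
    "wald_tests",
    "predict_cells",
    "residual_diagnostics",
    "analyze_all_traits",
    "implied_ar1_correlation",
]


@dataclass(frozen=True)
class ModelSpec:
    """Model configuration for one trait.

    ``factors`` are crossed (main effects + all interactions); ``block``
    enters additively. ``alpha`` is the significance level for LSDs.
    """

    response: str
    block: str | None = "Block"
    factors: tuple[str, ...] = ("Zn", "AMF")
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError(f"alpha={self.alpha} not in (0, 1)")
        if not self.factors:
            raise ParameterError("at least one treatment factor is required")
        object.__setattr__(self, "factors", tuple(self.factors))

    @property
    def rhs_formula(self) -> str:
        parts = []
        if self.block is not None:
            parts.append(f"C(Q('{self.block}'))")
        parts.append(" * ".join(f"C(Q('{f}'))" for f in self.factors))
        return " + ".join(["1"] + parts)


def _term_factor_names(term) -> frozenset:
    """Factor columns involved in a patsy term (for marginality)."""
    names = set()
    for f in term.factors:
        code = f.name()
        # C(Q('Zn')) -> Zn
        inner = code
        if "Q('" in inner:
            inner = inner.split("Q('", 1)[1].split("'", 1)[0]
        names.add(inner)
    return frozenset(names)


@dataclass
class AnalysisResult:
    """OLS fit of one trait under a :class:`ModelSpec`."""

    spec: ModelSpec
    data: pd.DataFrame            # analysed rows (response non-missing)
    design_info: object           # patsy DesignInfo of X
    X: np.ndarray
    y: np.ndarray
    beta: np.ndarray
    cov_unscaled: np.ndarray      # (X'X)^-1 (pseudo-inverse if needed)
    fitted: np.ndarray
    residuals: np.ndarray
    rss: float
    sigma2: float
    df_resid: int
    rank: int

    @property
    def term_names(self) -> list[str]:
        return [t.name() for t in self.design_info.terms if t.factors]


def _cell_counts(data: pd.DataFrame, factors: Sequence[str]) -> pd.Series:
    levels = [sorted(data[f].astype(str).unique()) for f in factors]
    combos = list(product(*levels))
    key = data[list(factors)].astype(str).agg(tuple, axis=1)
    counts = key.value_counts()
    return pd.Series({c: int(counts.get(c, 0)) for c in combos})


def fit_rcbd(table: TraitTable | pd.DataFrame, spec: ModelSpec) -> AnalysisResult:
    """Fit the fixed-effects RCBD model for ``spec.response`` by OLS.

    Rows with a missing response (removed plants) are dropped, making the
    least-squares problem unbalanced but otherwise unchanged. Empty
    treatment cells raise :class:`EstimabilityError` naming the cell;
    sigma^2 = RSS / df_resid.
    """
    df = table.data if isinstance(table, TraitTable) else table
    needed = [spec.response] + ([spec.block] if spec.block else []) + list(spec.factors)
    for c in needed:
        if c not in df.columns:
            raise SchemaError(f"column {c!r} not in trait table")
    sub = df[df[spec.response].notna()].copy()
    counts = _cell_counts(sub, spec.factors)
    empty = counts[counts == 0]
    if len(empty):
        cell = empty.index[0]
        desc = ", ".join(f"{f}={l}" for f, l in zip(spec.factors, cell))
        raise EstimabilityError(f"empty treatment cell: {desc}")

    X = patsy.dmatrix(spec.rhs_formula, sub, return_type="matrix")
    design_info = X.design_info
    X = np.asarray(X, dtype=float)
    y = sub[spec.response].to_numpy(dtype=float)
    n, p = X.shape
    rank = int(np.linalg.matrix_rank(X))
    df_resid = n - rank
    if df_resid < 1:
        raise ParameterError(
            f"no residual degrees of freedom (n={n}, rank={rank})"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    xtx = X.T @ X
    cov_unscaled = np.linalg.pinv(xtx)
    return AnalysisResult(
        spec=spec,
        data=sub,
        design_info=design_info,
        X=X,
        y=y,
        beta=beta,
        cov_unscaled=cov_unscaled,
        fitted=fitted,
        residuals=resid,
        rss=rss,
        sigma2=rss / df_resid,
        df_resid=df_resid,
        rank=rank,
    )


def _rss_for_columns(X: np.ndarray, y: np.ndarray, cols: np.ndarray) -> float:
    Q, _ = np.linalg.qr(X[:, cols])
    proj = Q.T @ y
    return float(y @ y - proj @ proj)


def _type2_sets(design_info):
    """Per testable term: column indices of the comparison models.

    Type II: SS(T) = RSS(model without T and without any term containing T)
    - RSS(model with T added, still excluding the containing terms).
    """
    terms = list(design_info.terms)
    slices = design_info.term_slices
    sets = {}
    for term in terms:
        if not term.factors:
            continue
        T = _term_factor_names(term)
        keep_base, keep_with = [], []
        for other in terms:
            sl = slices[other]
            idx = list(range(sl.start, sl.stop))
            O = _term_factor_names(other)
            contains_T = T <= O
            if other is term:
                keep_with += idx
            elif contains_T and other.factors:
                continue  # excluded from both models (higher-order)
            else:
                keep_base += idx
                keep_with += idx
        sets[term.name()] = (
            np.array(sorted(keep_base), dtype=int),
            np.array(sorted(keep_with), dtype=int),
            slices[term],
        )
    return sets


def wald_tests(fit: AnalysisResult) -> pd.DataFrame:
    """Marginality-respecting (Type II) Wald F tests for every model term.

    F = (SS_term / ndf) / sigma^2 with ddf = residual df. With zero
    residual variance (degenerate noiseless data) the F ratio is undefined
    and reported as missing with a note.
    """
    sets = _type2_sets(fit.design_info)
    # noiseless data leave a floating-point-sized RSS; treat it as zero
    yty = float(fit.y @ fit.y)
    sigma2 = fit.sigma2 if fit.rss > 1e-12 * (1.0 + yty) else 0.0
    rows = []
    for name, (base_cols, with_cols, sl) in sets.items():
        rss_base = _rss_for_columns(fit.X, fit.y, base_cols)
        rss_with = _rss_for_columns(fit.X, fit.y, with_cols)
        ndf = int(
            np.linalg.matrix_rank(fit.X[:, with_cols])
            - np.linalg.matrix_rank(fit.X[:, base_cols])
        )
        ss = max(rss_base - rss_with, 0.0)
        note = ""
        if sigma2 > 0 and ndf > 0:
            F = (ss / ndf) / sigma2
            p = float(stats.f.sf(F, ndf, fit.df_resid))
        else:
            F, p = np.nan, np.nan
            note = "zero residual variance" if sigma2 == 0 else "zero ndf"
        rows.append(
            {
                "term": _pretty_term(name),
                "F": F,
                "ndf": ndf,
                "ddf": fit.df_resid,
                "p": p,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def _pretty_term(name: str) -> str:
    """C(Q('Zn')):C(Q('AMF')) -> Zn:AMF"""
    out = []
    for part in name.split(":"):
        if "Q('" in part:
            part = part.split("Q('", 1)[1].split("'", 1)[0]
        out.append(part)
    return ":".join(out)


@dataclass
class Predictions:
    """Cell predictions with pairwise SEDs and LSDs.

    ``frame``: one row per treatment cell (estimate, SE, half_lsd for
    ribbon plotting); ``sed``/``lsd``: pairwise matrices (DataFrames
    indexed by cell label); ``lsd_summary``: t * mean(SED), the single
    number used for a ribbon when SEDs differ.
    """

    frame: pd.DataFrame
    sed: pd.DataFrame
    lsd: pd.DataFrame
    alpha: float
    t_crit: float
    lsd_summary: float


def predict_cells(fit: AnalysisResult, at: pd.DataFrame | None = None) -> Predictions:
    """Predicted values for treatment cells, averaging over blocks.

    ``at`` optionally restricts/orders the cells (a frame with one row per
    cell over the treatment factor columns); by default all observed
    factor-level combinations are predicted.
    """
    spec = fit.spec
    factors = list(spec.factors)
    if at is None:
        levels = [sorted(fit.data[f].unique().tolist()) for f in factors]
        at = pd.DataFrame(list(product(*levels)), columns=factors)
    blocks = (
        sorted(fit.data[spec.block].unique().tolist()) if spec.block else [None]
    )
    L_rows = []
    for _, cell in at.iterrows():
        reps = pd.DataFrame([cell] * len(blocks)).reset_index(drop=True)
        if spec.block:
            reps[spec.block] = blocks
        (M,) = patsy.build_design_matrices([fit.design_info], reps)
        L_rows.append(np.asarray(M, dtype=float).mean(axis=0))
    L = np.vstack(L_rows)

    est = L @ fit.beta
    V = fit.sigma2 * (L @ fit.cov_unscaled @ L.T)
    se = np.sqrt(np.clip(np.diag(V), 0.0, None))
    labels = at.astype(str).agg(":".join, axis=1).tolist()

    k = len(labels)
    sed = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                sed[i, j] = np.sqrt(max(V[i, i] + V[j, j] - 2.0 * V[i, j], 0.0))
    t_crit = float(stats.t.ppf(1.0 - spec.alpha / 2.0, fit.df_resid))
    lsd = t_crit * sed
    off = sed[~np.eye(k, dtype=bool)]
    lsd_summary = float(t_crit * off.mean()) if k > 1 else np.nan

    frame = at.copy()
    frame["estimate"] = est
    frame["SE"] = se
    frame["half_lsd"] = 0.5 * lsd_summary
    return Predictions(
        frame=frame,
        sed=pd.DataFrame(sed, index=labels, columns=labels),
        lsd=pd.DataFrame(lsd, index=labels, columns=labels),
        alpha=spec.alpha,
        t_crit=t_crit,
        lsd_summary=lsd_summary,
    )


def residual_diagnostics(fit: AnalysisResult) -> dict[str, pd.DataFrame]:
    """Tables for residual-vs-fitted and normal-probability plots.

    ``rvf``: fitted, residual, standardized residual per analysed row;
    ``qq``: ordered residuals against normal quantiles (Blom plotting
    positions). No formal normality statistic is computed — the assessment
    is visual.
    """
    sd = np.sqrt(fit.sigma2) if fit.sigma2 > 0 else np.nan
    rvf = pd.DataFrame(
        {
            "fitted": fit.fitted,
            "residual": fit.residuals,
            "standardized": fit.residuals / sd,
        }
    )
    n = len(fit.residuals)
    order = np.sort(fit.residuals)
    pp = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    qq = pd.DataFrame(
        {"theoretical": stats.norm.ppf(pp), "ordered_residual": order}
    )
    return {"rvf": rvf, "qq": qq}


@dataclass
class MultiTraitSummary:
    """Output of :func:`analyze_all_traits`."""

    frame: pd.DataFrame                      # trait x term rows
    fits: dict                               # trait -> AnalysisResult
    failures: dict                           # trait -> error message
    alpha: float

    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["significant"]]


def analyze_all_traits(
    table: TraitTable,
    spec_template: ModelSpec | None = None,
    traits: Sequence[str] | None = None,
) -> MultiTraitSummary:
    """Fit the RCBD model to every trait column; collect Wald summaries.

    Returns a long frame [trait, term, F, ndf, ddf, p, significant]
    mirroring the usual per-trait hypothesis-test summary table.
    Per-trait failures are collected, not fatal.

    When no trait has missing values the design matrix and the per-term QR
    factorizations are shared across traits, which makes large simulation
    studies (thousands of re-analyses) cheap.
    """
    if spec_template is None:
        spec_template = ModelSpec(response="", block=table.block)
    traits = list(traits) if traits is not None else list(table.traits)
    rows, fits, failures = [], {}, {}
    alpha = spec_template.alpha

    df = table.data
    complete = all(df[t].notna().all() for t in traits if t in df.columns)
    shared = None
    if complete and traits:
        try:
            spec0 = replace(spec_template, response=traits[0])
            fit0 = fit_rcbd(table, spec0)
            sets = _type2_sets(fit0.design_info)
            # orthonormal bases per column subset, shared across traits
            qmap = {}
            for base_cols, with_cols, _ in sets.values():
                for cols in (tuple(base_cols), tuple(with_cols)):
                    if cols not in qmap:
                        Q, _ = np.linalg.qr(fit0.X[:, list(cols)])
                        qmap[cols] = (Q, int(np.linalg.matrix_rank(fit0.X[:, list(cols)])))
            full_cols = tuple(range(fit0.X.shape[1]))
            Qfull, _ = np.linalg.qr(fit0.X)
            shared = (fit0, sets, qmap, Qfull)
        except Exception:
            shared = None

    for trait in traits:
        spec = replace(spec_template, response=trait)
        try:
            if shared is not None:
                fit0, sets, qmap, Qfull = shared
                y = df[trait].to_numpy(dtype=float)
                yy = float(y @ y)
                proj = Qfull.T @ y
                rss_full = yy - float(proj @ proj)
                df_resid = fit0.df_resid
                sigma2 = rss_full / df_resid
                for name, (base_cols, with_cols, _) in sets.items():
                    Qb, rb = qmap[tuple(base_cols)]
                    Qw, rw = qmap[tuple(with_cols)]
                    pb, pw = Qb.T @ y, Qw.T @ y
                    ss = max((yy - pb @ pb) - (yy - pw @ pw), 0.0)
                    ndf = rw - rb
                    if sigma2 > 0 and ndf > 0:
                        F = (ss / ndf) / sigma2
                        p = float(stats.f.sf(F, ndf, df_resid))
                    else:
                        F, p = np.nan, np.nan
                    rows.append(
                        {
                            "trait": trait,
                            "term": _pretty_term(name),
                            "F": F,
                            "ndf": ndf,
                            "ddf": df_resid,
                            "p": p,
                            "significant": bool(p <= alpha) if np.isfinite(p) else False,
                        }
                    )
            else:
                fit = fit_rcbd(table, spec)
                fits[trait] = fit
                wt = wald_tests(fit)
                for _, r in wt.iterrows():
                    rows.append(
                        {
                            "trait": trait,
                            "term": r["term"],
                            "F": r["F"],
                            "ndf": r["ndf"],
                            "ddf": r["ddf"],
                            "p": r["p"],
                            "significant": bool(r["p"] <= alpha)
                            if np.isfinite(r["p"])
                            else False,
                        }
                    )
        except Exception as exc:
            failures[trait] = str(exc)
    frame = pd.DataFrame(
        rows, columns=["trait", "term", "F", "ndf", "ddf", "p", "significant"]
    )
    return MultiTraitSummary(frame=frame, fits=fits, failures=failures, alpha=alpha)


def implied_ar1_correlation(rho: float, lag: int) -> float:
    """Correlation implied by a first-order autoregressive process at a
    given lag: rho ** lag (the power-law decay with the number of
    intervening time points)."""
    if not (-1.0 < rho < 1.0):
        raise ParameterError(f"|rho| must be < 1, got {rho}")
    if not (isinstance(lag, (int, np.integer)) and lag >= 1):
        raise ParameterError(f"lag must be a positive integer, got {lag!r}")
    return float(rho) ** int(lag)
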