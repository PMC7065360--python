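"""Evidence-based smoothing diagnostics.

Choosing a smoothing scheme (direct vs log scale, how many DF, spline vs
logistic) is kept a human decision, but an informed one. The tools here
summarize, per facet (e.g. AMF level or full treatment combination) and per
time point:

* **median deviations** — the median over subjects of observed minus
  smoothed values, one curve per candidate scheme. Medians above zero mean
  the smooth under-estimates the trend (or a positive transient occurred);
  below zero the opposite.
* **deviation envelope** — a +/- band equal to a fraction (default 10%) of
  the median smoothed trajectory of a reference scheme, giving the
  deviations a scale.
* **profile summaries** — per-time median and outer whiskers
  (median +/- 1.5 * IQR); trajectories wandering outside the whiskers are
  potential outliers.

The testable surface is the tables; small matplotlib helpers render the
standard plots from them.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import EmptyResultError, ParameterError
from .longdata import LongitudinalDataset

__all__ = [
    "median_deviations",
    "deviation_envelope",
    "profile_summary",
    "plot_profiles",
    "plot_median_deviations",
]

_ALL = "all"  # facet label when no facet column is given


def _facet_cols(ds: LongitudinalDataset, facet) -> list[str]:
    if facet is None:
        return []
    if isinstance(facet, str):
        facet = [facet]
    for f in facet:
        if f not in ds.data.columns:
            raise ParameterError(f"facet column {f!r} not in dataset")
    return list(facet)


def _facet_key(df: pd.DataFrame, cols: list[str]) -> pd.Series:
    if not cols:
        return pd.Series(_ALL, index=df.index)
    if len(cols) == 1:
        return df[cols[0]].astype(str)
    return df[cols].astype(str).agg(":".join, axis=1)


def _smoothed_frame(smoothed, trait: str) -> tuple[pd.DataFrame, str]:
    """Accept a SmoothResult or a LongitudinalDataset carrying s{trait}."""
    scol = f"s{trait}"
    if hasattr(smoothed, "dataset"):  # SmoothResult
        return smoothed.dataset.data, scol
    if isinstance(smoothed, LongitudinalDataset):
        if scol not in smoothed.data.columns:
            raise ParameterError(f"smoothed dataset lacks column {scol!r}")
        return smoothed.data, scol
    raise ParameterError(f"unsupported smoothed input of type {type(smoothed)!r}")


def median_deviations(
    observed: LongitudinalDataset,
    smoothed: Mapping[str, object],
    trait: str,
    facet=None,
) -> pd.DataFrame:
    """Median over subjects of (observed - smoothed), per scheme/facet/time.

    ``smoothed`` maps a scheme label to a SmoothResult (or a dataset already
    holding the smoothed column ``s{trait}``). Missing values are excluded
    from the medians. Returns a tidy frame with columns
    [scheme, facet, time, median_deviation, n].
    """
    fcols = _facet_cols(observed, facet)
    rows = []
    for label, sm in smoothed.items():
        sdf, scol = _smoothed_frame(sm, trait)
        key = [observed.subject, observed.time]
        merged = observed.data[key + fcols + [trait]].merge(
            sdf[key + [scol]], on=key, how="inner"
        )
        merged = merged[merged[trait].notna() & merged[scol].notna()]
        if merged.empty:
            raise EmptyResultError(
                f"scheme {label!r}: no overlapping (subject, time) keys with "
                "non-missing values"
            )
        merged["deviation"] = merged[trait] - merged[scol]
        merged["facet"] = _facet_key(merged, fcols)
        agg = (
            merged.groupby(["facet", observed.time])["deviation"]
            .agg(median_deviation="median", n="count")
            .reset_index()
            .rename(columns={observed.time: "time"})
        )
        agg.insert(0, "scheme", label)
        rows.append(agg)
    return pd.concat(rows, ignore_index=True)


def deviation_envelope(
    reference,
    trait: str | None = None,
    fraction: float = 0.10,
    facet=None,
    observed: LongitudinalDataset | None = None,
) -> pd.DataFrame:
    """Symmetric envelope +/- fraction * median(smoothed value).

    ``reference`` is the SmoothResult (or dataset) of the reference scheme,
    conventionally the chosen one (log-smoothing, 6 DF). The envelope is
    centered at zero: envelope_low = -envelope_high. Facet columns are read
    from ``observed`` if given, else from the reference dataset.
    """
    if fraction < 0:
        raise ParameterError("fraction must be >= 0")
    if trait is None and hasattr(reference, "trait"):
        trait = reference.trait
    if trait is None:
        raise ParameterError("trait must be given when reference is a dataset")
    sdf, scol = _smoothed_frame(reference, trait)
    base = observed if observed is not None else (
        reference.dataset if hasattr(reference, "dataset") else reference
    )
    fcols = _facet_cols(base, facet)
    frame = sdf[sdf[scol].notna()].copy()
    frame["facet"] = _facet_key(frame, fcols)
    time_col = base.time if isinstance(base, LongitudinalDataset) else "DAP"
    agg = (
        frame.groupby(["facet", time_col])[scol]
        .median()
        .reset_index()
        .rename(columns={time_col: "time", scol: "median_smoothed"})
    )
    agg["envelope_high"] = fraction * agg["median_smoothed"]
    agg["envelope_low"] = -agg["envelope_high"]
    return agg[["facet", "time", "median_smoothed", "envelope_low", "envelope_high"]]


def profile_summary(
    ds: LongitudinalDataset,
    trait: str,
    facet=None,
) -> pd.DataFrame:
    """Per (facet, time): median and outer whiskers median -/+ 1.5 * IQR.

    IQR is the 75th minus the 25th percentile, quantiles by linear
    interpolation between order statistics (the "type 7" convention,
    recorded in the ``quantile_method`` attribute of the result). Cells with
    no non-missing value are dropped.
    """
    if trait not in ds.data.columns:
        raise ParameterError(f"trait {trait!r} not in dataset")
    fcols = _facet_cols(ds, facet)
    frame = ds.data[ds.data[trait].notna()].copy()
    frame["facet"] = _facet_key(frame, fcols)
    g = frame.groupby(["facet", ds.time])[trait]
    out = g.agg(
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
        n="count",
    ).reset_index().rename(columns={ds.time: "time"})
    iqr = out["q3"] - out["q1"]
    out["whisker_low"] = out["median"] - 1.5 * iqr
    out["whisker_high"] = out["median"] + 1.5 * iqr
    out.attrs["quantile_method"] = "linear interpolation (type 7)"
    return out


# ---------------------------------------------------------------------------
# plotting (thin; the tables above are the tested surface)
# ---------------------------------------------------------------------------

def plot_profiles(ds: LongitudinalDataset, trait: str, facet=None, path=None):
    """Profile plot: one line per subject, black median line, dashed outer
    whiskers, faceted into panes. Returns the matplotlib Figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fcols = _facet_cols(ds, facet)
    frame = ds.data[ds.data[trait].notna()].copy()
    frame["facet"] = _facet_key(frame, fcols)
    summ = profile_summary(ds, trait, facet)
    levels = sorted(frame["facet"].unique())
    fig, axes = plt.subplots(
        1, len(levels), figsize=(4 * len(levels), 3.2), squeeze=False, sharey=True
    )
    for ax, lev in zip(axes[0], levels):
        pane = frame[frame["facet"] == lev]
        for _, sub in pane.groupby(ds.subject):
            ax.plot(sub[ds.time], sub[trait], lw=0.6, alpha=0.6)
        ps = summ[summ["facet"] == lev]
        ax.plot(ps["time"], ps["median"], color="black", lw=1.5)
        ax.plot(ps["time"], ps["whisker_low"], "k--", lw=1.0)
        ax.plot(ps["time"], ps["whisker_high"], "k--", lw=1.0)
        ax.set_title(str(lev))
        ax.set_xlabel(ds.time)
    axes[0][0].set_ylabel(trait)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_median_deviations(table: pd.DataFrame, envelope: pd.DataFrame | None = None,
                           path=None):
    """Median-deviations plot: one line per scheme per facet pane, optional
    dashed envelope. ``table`` is the output of :func:`median_deviations`."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    levels = sorted(table["facet"].unique())
    fig, axes = plt.subplots(
        1, len(levels), figsize=(4 * len(levels), 3.2), squeeze=False, sharey=True
    )
    for ax, lev in zip(axes[0], levels):
        pane = table[table["facet"] == lev]
        for label, grp in pane.groupby("scheme"):
            ax.plot(grp["time"], grp["median_deviation"], lw=1.0, label=str(label))
        if envelope is not None:
            env = envelope[envelope["facet"] == lev]
            ax.plot(env["time"], env["envelope_low"], "k--", lw=1.0)
            ax.plot(env["time"], env["envelope_high"], "k--", lw=1.0)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_title(str(lev))
        ax.set_xlabel("time")
    axes[0][0].set_ylabel("median deviation")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
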