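"""Extraction of per-subject growth traits from smoothed trajectories.

Given interval endpoints (e.g. DAP 18, 22, 27, 33, 39, 43, 51 for the
tomato-style experiment), the extracted traits are

* the smoothed trait value at each endpoint,
* optionally its continuous AGR and RGR at each endpoint,
* the mean AGR and RGR over each interval, computed from the smoothed
  endpoint values — by the telescoping identity this equals the
  time-weighted mean of the continuous smoothed GRs across the interval.

With ``e`` endpoints and all three per-endpoint traits this yields
``3e + 2(e-1)`` trait columns (33 for e = 7); dropping the endpoint GR
traits leaves ``e + 2(e-1)`` (19 for e = 7), the set conventionally taken
into the designed-experiment analysis, because endpoint GRs duplicate the
information in the neighbouring interval means.

Interval choice stays manual: growth dynamics, not an algorithm, dictate
sensible endpoints. :func:`interval_homogeneity_report` summarizes the
dynamics inside candidate intervals to support that choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ParameterError
from .diagnostics import _facet_cols, _facet_key
from .longdata import LongitudinalDataset, interval_gr

__all__ = ["IntervalSpec", "TraitTable", "extract_traits", "interval_homogeneity_report"]


@dataclass(frozen=True)
class IntervalSpec:
    """Ordered interval endpoint times; k endpoints define k-1 intervals."""

    endpoints: tuple[int, ...]

    def __post_init__(self) -> None:
        ep = tuple(int(e) for e in self.endpoints)
        if len(ep) < 2:
            raise ParameterError("need at least 2 endpoints")
        if any(b <= a for a, b in zip(ep, ep[1:])):
            raise ParameterError(f"endpoints must be strictly increasing: {ep}")
        object.__setattr__(self, "endpoints", ep)

    @property
    def intervals(self) -> list[tuple[int, int]]:
        return list(zip(self.endpoints[:-1], self.endpoints[1:]))


@dataclass
class TraitTable:
    """One row per subject: design/treatment factors plus extracted traits.

    ``data`` is indexed by subject; ``factors`` lists the design columns
    (block first when present) and ``traits`` the extracted trait columns
    in canonical order.
    """

    data: pd.DataFrame
    factors: tuple[str, ...]
    traits: tuple[str, ...]
    block: str | None = "Block"

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path, float_format: str = "%.6g") -> None:
        self.data.to_csv(path, float_format=float_format)


def _resolve_dataset(smoothed) -> LongitudinalDataset:
    if hasattr(smoothed, "dataset"):  # SmoothResult
        return smoothed.dataset
    if isinstance(smoothed, LongitudinalDataset):
        return smoothed
    raise ParameterError(f"unsupported input of type {type(smoothed)!r}")


def extract_traits(
    smoothed,
    spec: IntervalSpec,
    trait: str = "sPSA",
    include_endpoint_gr: bool = True,
) -> TraitTable:
    """Build the per-subject trait table from a smoothed dataset.

    ``smoothed`` is a SmoothResult or a dataset holding ``trait`` and its
    continuous GR columns ``{trait}.AGR`` / ``{trait}.RGR`` (needed only
    when ``include_endpoint_gr``). Column naming: ``sPSA.33`` for endpoint
    values, ``sPSA.AGR.33`` for endpoint GRs, ``sPSA.AGR.33_39`` for
    interval means.

    Endpoints missing for a subject yield missing entries (with a recorded
    warning in ``table.data.attrs['warnings']``), not a global failure.
    """
    ds = _resolve_dataset(smoothed)
    if trait not in ds.data.columns:
        raise ParameterError(f"trait {trait!r} not in dataset")
    wide = ds.data.pivot(index=ds.subject, columns=ds.time, values=trait)
    warnings: list[str] = []

    cols: dict[str, pd.Series] = {}
    order: list[str] = []

    # endpoint values
    for d in spec.endpoints:
        name = f"{trait}.{d}"
        if d in wide.columns:
            cols[name] = wide[d]
            nmiss = int(wide[d].isna().sum())
            if nmiss:
                warnings.append(f"{name}: missing for {nmiss} subject(s)")
        else:
            cols[name] = pd.Series(np.nan, index=wide.index)
            warnings.append(f"{name}: endpoint time {d} not in smoothed grid")
        order.append(name)

    # endpoint GRs (continuous, from the smoothed trajectory)
    if include_endpoint_gr:
        for kind in ("AGR", "RGR"):
            gcol = f"{trait}.{kind}"
            if gcol not in ds.data.columns:
                raise ParameterError(
                    f"column {gcol!r} absent; derive continuous GRs before "
                    "extracting endpoint GR traits"
                )
            gwide = ds.data.pivot(index=ds.subject, columns=ds.time, values=gcol)
            for d in spec.endpoints:
                name = f"{gcol}.{d}"
                cols[name] = (
                    gwide[d] if d in gwide.columns
                    else pd.Series(np.nan, index=wide.index)
                )
                order.append(name)

    # interval mean GRs from the smoothed endpoint values
    for kind in ("AGR", "RGR"):
        for a, b in spec.intervals:
            name = f"{trait}.{kind}.{a}_{b}"
            try:
                cols[name] = interval_gr(ds, trait, a, b, kind=kind)
            except Exception as exc:  # endpoint absent for some subject
                cols[name] = pd.Series(np.nan, index=wide.index)
                warnings.append(f"{name}: {exc}")
            order.append(name)

    table = pd.DataFrame(cols, index=wide.index)[order]
    factors = ds.factor_frame()
    out = factors.join(table)
    out.attrs["warnings"] = warnings
    return TraitTable(
        data=out,
        factors=tuple(factors.columns),
        traits=tuple(order),
        block=ds.block,
    )


def interval_homogeneity_report(
    smoothed,
    spec: IntervalSpec,
    trait: str = "sPSA",
    facet=None,
    flat_tol: float = 0.05,
) -> pd.DataFrame:
    """Decision-support summary of growth dynamics inside each interval.

    Per interval and facet level: the median continuous AGR at the interval
    start and end, the sign of the median-AGR slope, the trend of the median
    RGR, the fraction of subjects whose AGR increased over the interval,
    and a coarse category label ("AGR increasing", "AGR decreasing",
    "AGR steady", "biomass unchanged", "biomass decreasing"). ``flat_tol``
    is the relative margin below which a change counts as flat.

    The report supports, and never replaces, the human interval choice.
    """
    ds = _resolve_dataset(smoothed)
    agr_col, rgr_col = f"{trait}.AGR", f"{trait}.RGR"
    for c in (agr_col, rgr_col):
        if c not in ds.data.columns:
            raise ParameterError(f"column {c!r} absent; smooth + derive GRs first")
    fcols = _facet_cols(ds, facet)
    frame = ds.data.copy()
    frame["facet"] = _facet_key(frame, fcols)
    scale = float(frame[agr_col].abs().median() or 1.0)

    rows = []
    for a, b in spec.intervals:
        inside = frame[frame[ds.time].between(a, b)]
        for fac, sub in inside.groupby("facet"):
            med = sub.groupby(ds.time)[[agr_col, rgr_col]].median()
            # first/last times in the interval with a defined AGR
            med_a = med[agr_col].dropna()
            med_r = med[rgr_col].dropna()
            agr_start = float(med_a.iloc[0]) if len(med_a) else np.nan
            agr_end = float(med_a.iloc[-1]) if len(med_a) else np.nan
            rgr_slope = (
                float(med_r.iloc[-1] - med_r.iloc[0]) if len(med_r) > 1 else np.nan
            )
            per_subj = sub[sub[agr_col].notna()].groupby(ds.subject)[agr_col]
            frac_inc = float(
                (per_subj.last() > per_subj.first()).mean()
            ) if per_subj.ngroups else np.nan
            delta = agr_end - agr_start
            med_level = float(np.nanmedian(med_a)) if len(med_a) else np.nan
            if np.isnan(delta):
                category = "insufficient data"
            elif abs(med_level) < flat_tol * scale:
                category = "biomass unchanged"
            elif med_level < 0:
                category = "biomass decreasing"
            elif delta > flat_tol * scale:
                category = "AGR increasing"
            elif delta < -flat_tol * scale:
                category = "AGR decreasing"
            else:
                category = "AGR steady"
            rows.append(
                {
                    "interval": f"{a}_{b}",
                    "facet": fac,
                    "median_agr_start": agr_start,
                    "median_agr_end": agr_end,
                    "median_agr": med_level,
                    "agr_slope_sign": int(np.sign(delta)) if not np.isnan(delta) else 0,
                    "median_rgr_change": rgr_slope,
                    "frac_subjects_agr_increasing": frac_inc,
                    "category": category,
                }
            )
    return pd.DataFrame(rows)
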