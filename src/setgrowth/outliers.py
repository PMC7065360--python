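"""Flagging and removal of anomalous subjects.

Three rules are implemented, all producing an :class:`OutlierReport` whose
every flagged (subject, time) is reproducible from the rule and its inputs:

* **whisker** — trait values strictly outside the per-facet outer whiskers
  (median +/- 1.5 * IQR across subjects at a time point) at a run of at
  least ``min_times`` consecutive observed times;
* **threshold** — smoothed values below/above user bounds inside a time
  interval, optionally with facet-specific bounds (thresholds often differ
  between treatments);
* **near_zero_gr** — growth rate near zero while the bulk of the facet is
  growing (an operationalization of "AGR/RGR close to zero when the bulk of
  plants are not": |GR| < eps while the facet median GR exceeds k * eps).

Removal is never automatic: the pipeline emits the report, and an explicit
subject list must be passed to :func:`remove_subjects` — it is advisable to
verify (lab books, images) that something irregular happened to a plant
before excluding it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ParameterError
from .diagnostics import _facet_cols, _facet_key, profile_summary
from .longdata import LongitudinalDataset

__all__ = [
    "OutlierReport",
    "flag_whisker",
    "flag_threshold",
    "flag_near_zero_gr",
    "remove_subjects",
]


@dataclass
class OutlierReport:
    """Tidy report of flagged subjects.

    ``frame`` has one row per flagged subject with columns
    [subject, rule, trait, facet, times] where ``times`` is the ordered
    list of flagged time points.
    """

    frame: pd.DataFrame
    rule: str
    params: dict

    _COLS = ["subject", "rule", "trait", "facet", "times"]

    @classmethod
    def empty(cls, rule: str, params: dict) -> "OutlierReport":
        return cls(pd.DataFrame(columns=cls._COLS), rule, params)

    @property
    def subjects(self) -> list:
        return list(self.frame["subject"]) if len(self.frame) else []

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        if len(out):
            out["times"] = out["times"].map(
                lambda ts: ";".join(str(t) for t in ts)
            )
        out.to_csv(path, index=False)


def _max_run(mask: np.ndarray) -> int:
    """Longest run of consecutive True values."""
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def flag_whisker(
    ds: LongitudinalDataset,
    trait: str,
    facet=None,
    min_times: int = 3,
    consecutive: bool = True,
) -> OutlierReport:
    """Flag subjects whose ``trait`` lies strictly outside the outer
    whiskers of their facet at >= ``min_times`` (by default consecutive)
    observed time points.

    A single-day excursion is usually a transient, hence the consecutive-run
    default; pass ``consecutive=False`` to count any ``min_times`` times.
    """
    if min_times < 1:
        raise ParameterError("min_times must be >= 1")
    summ = profile_summary(ds, trait, facet)
    fcols = _facet_cols(ds, facet)
    frame = ds.data[ds.data[trait].notna()].copy()
    frame["facet"] = _facet_key(frame, fcols)
    merged = frame.merge(
        summ[["facet", "time", "whisker_low", "whisker_high"]],
        left_on=["facet", ds.time],
        right_on=["facet", "time"],
        how="left",
    )
    merged["outside"] = (merged[trait] < merged["whisker_low"]) | (
        merged[trait] > merged["whisker_high"]
    )
    rows = []
    for (sid, fac), sub in merged.groupby([ds.subject, "facet"], sort=False):
        sub = sub.sort_values(ds.time)
        outside = sub["outside"].to_numpy()
        hits = _max_run(outside) if consecutive else int(outside.sum())
        if hits >= min_times:
            rows.append(
                {
                    "subject": sid,
                    "rule": "whisker",
                    "trait": trait,
                    "facet": fac,
                    "times": sub.loc[sub["outside"], ds.time].tolist(),
                }
            )
    params = {"min_times": min_times, "consecutive": consecutive, "facet": facet}
    if not rows:
        return OutlierReport.empty("whisker", params)
    return OutlierReport(pd.DataFrame(rows), "whisker", params)


def _bound_for(bound, fac):
    if bound is None:
        return None
    if isinstance(bound, Mapping):
        return bound.get(fac)
    return bound


def flag_threshold(
    ds: LongitudinalDataset,
    trait: str,
    interval: tuple[int, int],
    low=None,
    high=None,
    facet=None,
) -> OutlierReport:
    """Flag subjects with any ``trait`` value below ``low`` or above
    ``high`` inside ``interval`` = (t1, t2), endpoints inclusive.

    ``low``/``high`` may be scalars or ``{facet level: bound}`` mappings
    (thresholds often differ between treatments). At least one bound is
    required.
    """
    t1, t2 = interval
    if t1 > t2:
        raise ParameterError(f"interval start {t1} > end {t2}")
    if low is None and high is None:
        raise ParameterError("at least one of low/high must be given")
    fcols = _facet_cols(ds, facet)
    frame = ds.data[
        ds.data[trait].notna()
        & ds.data[ds.time].between(t1, t2)
    ].copy()
    frame["facet"] = _facet_key(frame, fcols)
    rows = []
    for (sid, fac), sub in frame.groupby([ds.subject, "facet"], sort=False):
        lo = _bound_for(low, fac)
        hi = _bound_for(high, fac)
        viol = pd.Series(False, index=sub.index)
        rule_parts = []
        if lo is not None:
            viol |= sub[trait] < lo
            rule_parts.append("threshold_low")
        if hi is not None:
            viol |= sub[trait] > hi
            rule_parts.append("threshold_high")
        if viol.any():
            rows.append(
                {
                    "subject": sid,
                    "rule": "+".join(rule_parts),
                    "trait": trait,
                    "facet": fac,
                    "times": sub.loc[viol, ds.time].tolist(),
                }
            )
    params = {"interval": (t1, t2), "low": low, "high": high, "facet": facet}
    if not rows:
        return OutlierReport.empty("threshold", params)
    return OutlierReport(pd.DataFrame(rows), "threshold", params)


def flag_near_zero_gr(
    ds: LongitudinalDataset,
    gr_trait: str,
    facet=None,
    eps: float | None = None,
    k: float = 5.0,
    min_times: int = 3,
) -> OutlierReport:
    """Flag subjects whose growth rate sits near zero while the bulk of
    their facet is growing.

    A time point counts when |GR| < eps and the facet median GR > k * eps;
    a subject is flagged at >= ``min_times`` such points. ``eps`` defaults
    to 5% of the global median |GR| (a data-scale heuristic; there is no
    canonical cutoff for "close to zero").
    """
    if gr_trait not in ds.data.columns:
        raise ParameterError(f"column {gr_trait!r} not in dataset")
    frame = ds.data[ds.data[gr_trait].notna()].copy()
    if eps is None:
        scale = float(frame[gr_trait].abs().median())
        eps = 0.05 * scale
    fcols = _facet_cols(ds, facet)
    frame["facet"] = _facet_key(frame, fcols)
    med = (
        frame.groupby(["facet", ds.time])[gr_trait]
        .median()
        .rename("facet_median")
        .reset_index()
    )
    merged = frame.merge(med, on=["facet", ds.time])
    merged["hit"] = (merged[gr_trait].abs() < eps) & (
        merged["facet_median"] > k * eps
    )
    rows = []
    for (sid, fac), sub in merged.groupby([ds.subject, "facet"], sort=False):
        if int(sub["hit"].sum()) >= min_times:
            rows.append(
                {
                    "subject": sid,
                    "rule": "near_zero_gr",
                    "trait": gr_trait,
                    "facet": fac,
                    "times": sub.loc[sub["hit"], ds.time].tolist(),
                }
            )
    params = {"eps": eps, "k": k, "min_times": min_times, "facet": facet}
    if not rows:
        return OutlierReport.empty("near_zero_gr", params)
    return OutlierReport(pd.DataFrame(rows), "near_zero_gr", params)


def remove_subjects(
    ds: LongitudinalDataset,
    ids: Sequence,
    reason: str | None = None,
) -> LongitudinalDataset:
    """Return the dataset without the listed subjects.

    Unknown ids raise :class:`ParameterError`. The removal (with its stated
    reason) is appended to the dataset history so downstream outputs carry
    the provenance. Downstream designed-experiment analyses become
    unbalanced; the analysis module handles that.
    """
    ids = list(ids)
    known = set(ds.subjects)
    unknown = [i for i in ids if i not in known]
    if unknown:
        raise ParameterError(f"unknown subject ids: {unknown}")
    if not ids:
        return ds
    out = ds.with_data(ds.data[~ds.data[ds.subject].isin(ids)].copy())
    note = f"removed subjects {ids}" + (f" ({reason})" if reason else "")
    return out.add_history(note)
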