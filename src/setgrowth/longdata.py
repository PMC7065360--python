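"""Longitudinal phenotype data model and growth-rate calculus.

The central container is :class:`LongitudinalDataset`: a long-format table
with one row per subject (plant/cart) per imaging time (integer days after
planting, DAP), carrying design factors (block, lane, position), treatment
factors and one or more nonnegative trait columns such as the projected
shoot area (PSA, kilopixels).

Growth rates follow the standard difference calculus: between two times
``t_j < t_k`` the absolute growth rate (AGR) is ``(y_k - y_j)/(t_k - t_j)``
and the relative growth rate (RGR) is ``(ln y_k - ln y_j)/(t_k - t_j)``.
"Continuous" rates are these quantities for consecutive observed times;
"interval" rates use the interval endpoints and equal the time-weighted
mean of the continuous rates inside the interval (a telescoping identity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import (
    DomainError,
    IntegrityError,
    MissingEndpointError,
    ParameterError,
    ParseError,
    SchemaError,
)

__all__ = [
    "LongitudinalDataset",
    "read_longitudinal",
    "derive_continuous_gr",
    "interval_gr",
]

#: default strings interpreted as missing values in CSV input
DEFAULT_MISSING_CODES = ("", "NA")


@dataclass
class LongitudinalDataset:
    """Long-format subject x time trait records with design metadata.

    Parameters
    ----------
    data
        One row per (subject, time). Sorted by (subject, time) on
        construction.
    subject, time
        Column names for the subject identifier and the integer time (DAP).
    block
        Column name of the blocking factor, or None for unblocked data.
    factors
        Treatment factor column names (e.g. ``("Zn", "AMF")``).
    traits
        Trait column names (primary traits plus any derived GR columns).

    Invariants enforced on construction: (subject, time) keys are unique and
    times are strictly increasing within a subject (guaranteed by sorting
    plus the uniqueness check). Positivity of primary traits is *not*
    enforced here; operations that need it (log smoothing, RGR) check it and
    raise :class:`~setgrowth._errors.DomainError`.
    """

    data: pd.DataFrame
    subject: str = "subject"
    time: str = "DAP"
    block: str | None = "Block"
    factors: tuple[str, ...] = ()
    traits: tuple[str, ...] = ("PSA",)
    history: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        cols = [self.subject, self.time]
        if self.block is not None:
            cols.append(self.block)
        cols += list(self.factors) + list(self.traits)
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise SchemaError(f"dataset is missing columns: {missing}")
        if not np.issubdtype(np.asarray(self.data[self.time]).dtype, np.integer):
            t = pd.to_numeric(self.data[self.time], errors="coerce")
            if t.isna().any() or (t != t.round()).any():
                raise ParseError(f"time column {self.time!r} is not integer-valued")
            self.data = self.data.assign(**{self.time: t.astype(int)})
        dup = self.data.duplicated([self.subject, self.time])
        if dup.any():
            key = self.data.loc[dup.idxmax(), [self.subject, self.time]]
            raise IntegrityError(
                f"duplicate (subject, time) key: ({key.iloc[0]!r}, {key.iloc[1]!r})"
            )
        self.data = (
            self.data.sort_values([self.subject, self.time], kind="mergesort")
            .reset_index(drop=True)
        )
        self.factors = tuple(self.factors)
        self.traits = tuple(self.traits)

    # -- simple accessors -------------------------------------------------

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.data[self.subject]))

    @property
    def times(self) -> np.ndarray:
        return np.sort(pd.unique(self.data[self.time]))

    def n_records(self, trait: str | None = None) -> int:
        """Number of rows, or of non-missing values of ``trait``."""
        if trait is None:
            return len(self.data)
        return int(self.data[trait].notna().sum())

    def subject_frame(self, subject_id) -> pd.DataFrame:
        return self.data[self.data[self.subject] == subject_id]

    def factor_frame(self) -> pd.DataFrame:
        """One row per subject with its design/treatment factor levels."""
        cols = [self.subject]
        if self.block is not None:
            cols.append(self.block)
        cols += list(self.factors)
        return (
            self.data[cols].drop_duplicates(self.subject).set_index(self.subject)
        )

    def with_data(self, data: pd.DataFrame, **changes) -> "LongitudinalDataset":
        return replace(self, data=data, **changes)

    def add_history(self, entry: str) -> "LongitudinalDataset":
        return replace(self, history=self.history + (entry,))

    def to_csv(self, path, float_format: str = "%.6g") -> None:
        self.data.to_csv(path, index=False, float_format=float_format)


def _resolve_map(column_map: Mapping) -> tuple[dict, list[str], list[str]]:
    """Normalize a logical->physical column map.

    ``factors`` and ``traits`` entries may be sequences of physical names
    (kept as-is) or ``{logical: physical}`` dicts (renamed on read).
    Returns (rename map physical->logical, factor names, trait names).
    """
    rename: dict[str, str] = {}
    for key in ("subject", "time", "block"):
        phys = column_map.get(key)
        if phys is not None:
            rename[phys] = phys  # presence checked later; no rename for core
    def _norm(entry) -> list[str]:
        if entry is None:
            return []
        if isinstance(entry, Mapping):
            for logical, phys in entry.items():
                rename[phys] = logical
            return list(entry.keys())
        return list(entry)
    factors = _norm(column_map.get("factors"))
    traits = _norm(column_map.get("traits"))
    return rename, factors, traits


def read_longitudinal(
    path,
    column_map: Mapping,
    missing_codes: Sequence[str] = DEFAULT_MISSING_CODES,
) -> LongitudinalDataset:
    """Read a long-format CSV into a :class:`LongitudinalDataset`.

    Parameters
    ----------
    path
        CSV file, one row per subject x time.
    column_map
        Mapping with keys ``subject``, ``time``, optionally ``block``, and
        ``factors`` / ``traits`` given either as lists of physical column
        names or as ``{logical: physical}`` dicts (physical columns are
        renamed to the logical names).
    missing_codes
        Strings treated as missing trait values.

    Raises
    ------
    SchemaError
        if a mapped column is absent.
    ParseError
        if the time column does not parse to integers, or a trait cell is
        neither numeric nor a missing code.
    IntegrityError
        on duplicated (subject, time) keys.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    for key in ("subject", "time"):
        if key not in column_map:
            raise SchemaError(f"column_map must provide a {key!r} entry")
    rename, factors, traits = _resolve_map(column_map)
    if not traits:
        raise SchemaError("column_map must name at least one trait column")

    df = pd.read_csv(
        path, dtype=str, na_values=list(missing_codes), keep_default_na=False
    )
    phys_needed = [column_map["subject"], column_map["time"]]
    if column_map.get("block"):
        phys_needed.append(column_map["block"])
    for entry in ("factors", "traits"):
        val = column_map.get(entry)
        if isinstance(val, Mapping):
            phys_needed += list(val.values())
        elif val is not None:
            phys_needed += list(val)
    missing_cols = [c for c in phys_needed if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"mapped columns absent from {path.name}: {missing_cols}")

    df = df.rename(
        columns={
            **{p: l for p, l in rename.items() if p != l},
            column_map["subject"]: "subject",
            column_map["time"]: "DAP",
        }
    )
    block = None
    if column_map.get("block"):
        df = df.rename(columns={column_map["block"]: "Block"})
        block = "Block"

    t = pd.to_numeric(df["DAP"], errors="coerce")
    if t.isna().any() and df["DAP"].notna().any():
        bad = df["DAP"][t.isna()].iloc[0]
        raise ParseError(f"time value {bad!r} does not parse to an integer")

    for trait in traits:
        raw = df[trait]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna()
        if bad.any():
            raise ParseError(
                f"non-numeric value {raw[bad].iloc[0]!r} in trait column {trait!r}"
            )
        df[trait] = num

    return LongitudinalDataset(
        data=df,
        subject="subject",
        time="DAP",
        block=block,
        factors=tuple(factors),
        traits=tuple(traits),
    )


def derive_continuous_gr(
    ds: LongitudinalDataset,
    trait: str,
    on_nonpositive: str = "raise",
) -> LongitudinalDataset:
    """Add continuous AGR and RGR columns derived from ``trait``.

    For each subject the AGR at time ``t_k`` is the difference of
    consecutive observed values divided by the actual time difference, and
    the RGR is the difference of natural logarithms over the same gap. The
    first observed time of each subject gets no value. Missing trait values
    propagate: the next observed difference spans the gap.

    The new columns are named ``{trait}.AGR`` and ``{trait}.RGR``; re-running
    overwrites them with identical values (idempotent).

    Parameters
    ----------
    on_nonpositive
        ``"raise"`` (default): a nonpositive value encountered for the RGR
        raises :class:`DomainError` naming subject and time. ``"missing"``:
        the RGR is simply missing wherever a log is undefined (used for
        smoothed direct-scale trajectories that may dip below zero).
    """
    if trait not in ds.data.columns:
        raise SchemaError(f"trait {trait!r} not in dataset")
    if on_nonpositive not in ("raise", "missing"):
        raise ParameterError(f"on_nonpositive must be 'raise' or 'missing'")
    df = ds.data.copy()
    present = df[df[trait].notna()]
    nonpos = present[present[trait] <= 0]
    if len(nonpos) and on_nonpositive == "raise":
        row = nonpos.iloc[0]
        raise DomainError(
            f"nonpositive {trait}={row[trait]} for subject {row[ds.subject]!r} "
            f"at {ds.time}={row[ds.time]}: RGR undefined"
        )

    sub = df[ds.subject]
    # differences over rows where the trait is observed, per subject
    obs = df[trait].notna()
    vals = df.loc[obs, trait].astype(float)
    times = df.loc[obs, ds.time].astype(float)
    g = sub[obs]
    dt = times.groupby(g).diff()
    agr = vals.groupby(g).diff() / dt
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = pd.Series(
            np.where(vals > 0, np.log(vals.where(vals > 0)), np.nan),
            index=vals.index,
        )
    rgr = logs.groupby(g).diff() / dt

    df[f"{trait}.AGR"] = agr.reindex(df.index)
    df[f"{trait}.RGR"] = rgr.reindex(df.index)
    new_traits = tuple(
        dict.fromkeys(list(ds.traits) + [f"{trait}.AGR", f"{trait}.RGR"])
    )
    return ds.with_data(df, traits=new_traits)


def interval_gr(
    ds: LongitudinalDataset,
    trait: str,
    t_start: int,
    t_end: int,
    kind: str = "AGR",
) -> pd.Series:
    """Per-subject interval growth rate between two endpoint times.

    AGR over [a, b] is ``(y_b - y_a)/(b - a)``; RGR uses the logs. By the
    telescoping identity this equals the time-weighted mean of the
    continuous rates of all consecutive observation pairs inside [a, b].

    Returns a Series indexed by subject, named ``{trait}.{kind}.{a}_{b}``.
    Missing if either endpoint *value* is missing; raises
    :class:`MissingEndpointError` if an endpoint *time* is absent from a
    subject's grid altogether.
    """
    if t_start >= t_end:
        raise ParameterError(f"t_start={t_start} must be < t_end={t_end}")
    if kind not in ("AGR", "RGR"):
        raise ParameterError(f"kind must be 'AGR' or 'RGR', got {kind!r}")
    if trait not in ds.data.columns:
        raise SchemaError(f"trait {trait!r} not in dataset")

    wide = ds.data.pivot(index=ds.subject, columns=ds.time, values=trait)
    present = ds.data.assign(_row=1.0).pivot(
        index=ds.subject, columns=ds.time, values="_row"
    )
    for t in (t_start, t_end):
        if t not in present.columns:
            absent = present.index.tolist()
        else:
            absent = present.index[present[t].isna()].tolist()
        if absent:
            raise MissingEndpointError(
                f"endpoint time {t} has no observed or imputed row for subjects "
                f"{absent[:5]}{'...' if len(absent) > 5 else ''}"
            )
    span = float(t_end - t_start)
    a, b = wide[t_start], wide[t_end]
    if kind == "AGR":
        out = (b - a) / span
    else:
        bad = ((a <= 0) & a.notna()) | ((b <= 0) & b.notna())
        if bad.any():
            raise DomainError(
                f"nonpositive {trait} at an endpoint for subject "
                f"{bad.idxmax()!r}: interval RGR undefined"
            )
        out = (np.log(b) - np.log(a)) / span
    out.name = f"{trait}.{kind}.{t_start}_{t_end}"
    return out
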