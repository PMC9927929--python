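"""Sparse clinical time series: data model, CSV I/O, validation.

A :class:`SampledSeries` holds one analyte's measurements for one subject on
an irregular time grid (hours). Missing samples are represented by absence of
the row — both the Lomb-Scargle periodogram and cosinor regression operate
natively on irregular grids, so a series with a dropped sample needs no
special handling downstream.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Timescale",
    "SampledSeries",
    "read_series_table",
    "write_series_table",
    "read_event_times",
    "zscore_series",
    "MIN_SAMPLES",
    "MIN_SPAN_H",
]

#: Minimum usable number of samples for any fitting operation. The nominal
#: sampling design is 7 points over 24 h or 13 over 48 h at 4-h spacing, and
#: one missing sample is tolerated.
MIN_SAMPLES = 5

#: Minimum observation span (hours) for circadian analysis.
MIN_SPAN_H = 20.0


class Timescale(enum.Enum):
    """Reference timescale of the sample times."""

    CLOCK_TIME = "clock_time"  # time of day, hours
    POST_EVENT = "post_event"  # hours since an external event (e.g. reperfusion)


@dataclass(frozen=True)
class SampledSeries:
    """One analyte's irregular time series for one subject.

    Parameters
    ----------
    subject_id, analyte
        Opaque labels (e.g. patient code and clock-gene symbol).
    times
        Sample times in hours, strictly increasing.
    values
        Measurements in arbitrary expression units, same length as times.
    timescale
        Whether times are clock time or hours post-event.
    """

    subject_id: str
    analyte: str
    times: np.ndarray
    values: np.ndarray
    timescale: Timescale = Timescale.CLOCK_TIME
    group: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D and equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError(
                f"times must be strictly increasing for ({self.subject_id}, {self.analyte})"
            )
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
            raise ValueError(
                f"non-finite time or value in ({self.subject_id}, {self.analyte})"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> float:
        """Observation span in hours."""
        return float(self.times[-1] - self.times[0]) if self.n else 0.0

    @property
    def usable(self) -> bool:
        """Whether the series meets the minimum requirements for fitting."""
        return self.n >= MIN_SAMPLES

    def require_usable(self) -> None:
        if not self.usable:
            raise ValueError(
                f"series ({self.subject_id}, {self.analyte}) has {self.n} samples; "
                f"at least {MIN_SAMPLES} required"
            )

    def with_values(self, values: np.ndarray) -> "SampledSeries":
        return replace(self, values=np.asarray(values, dtype=float))


def read_series_table(
    path: str | Path, timescale: Timescale | str = Timescale.CLOCK_TIME
) -> list[SampledSeries]:
    """Read a long-format CSV of time series.

    Expected header: ``subject,analyte,time_h,value`` with an optional
    ``group`` column. Rows with a missing value are dropped with a warning.
    Series with fewer than :data:`MIN_SAMPLES` usable points are returned
    flagged (``usable == False``) rather than silently dropped.

    Raises
    ------
    ValueError
        If a (subject, analyte, time) triple is duplicated, naming the triple.
    """
    if isinstance(timescale, str):
        timescale = Timescale(timescale)
    df = pd.read_csv(path)
    required = {"subject", "analyte", "time_h", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")

    dup = df.duplicated(subset=["subject", "analyte", "time_h"], keep=False)
    if dup.any():
        r = df[dup].iloc[0]
        raise ValueError(
            f"duplicate sample: {r['subject']}, {r['analyte']}, {r['time_h']}"
        )

    n_missing = int(df["value"].isna().sum())
    if n_missing:
        warnings.warn(
            f"dropped {n_missing} row(s) with missing value", stacklevel=2
        )
        df = df.dropna(subset=["value"])

    out: list[SampledSeries] = []
    for (subject, analyte), g in df.groupby(["subject", "analyte"], sort=True):
        g = g.sort_values("time_h")
        group = None
        if "group" in g.columns and g["group"].notna().any():
            group = str(g["group"].dropna().iloc[0])
        out.append(
            SampledSeries(
                subject_id=str(subject),
                analyte=str(analyte),
                times=g["time_h"].to_numpy(float),
                values=g["value"].to_numpy(float),
                timescale=timescale,
                group=group,
            )
        )
    return out


def write_series_table(series: Iterable[SampledSeries], path: str | Path) -> None:
    """Write series back to the long-format CSV dialect read by
    :func:`read_series_table` (comma-separated, '.' decimal, header)."""
    rows = []
    for s in series:
        for t, v in zip(s.times, s.values):
            row = {"subject": s.subject_id, "analyte": s.analyte, "time_h": t, "value": v}
            if s.group is not None:
                row["group"] = s.group
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_event_times(path: str | Path) -> pd.DataFrame:
    """Read an event-time CSV with columns ``subject,event_time_h[,outcome]``.

    Event times are clock hours on the 24-h circle.
    """
    df = pd.read_csv(path)
    required = {"subject", "event_time_h"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    t = df["event_time_h"].to_numpy(float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite event time")
    df["event_time_h"] = np.mod(t, 24.0)
    return df


def zscore_series(s: SampledSeries) -> SampledSeries:
    """Standardize values to sample mean 0 and SD 1 (ddof=1).

    Times and metadata are unchanged. Raises on a constant series.
    """
    v = s.values
    if s.n < 2:
        raise ValueError("need at least 2 samples to standardize")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError(
            f"zero variance in ({s.subject_id}, {s.analyte}); cannot standardize"
        )
    return s.with_values((v - v.mean()) / sd)
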