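"""Core containers for aligned batch-process data.

A manufacturing campaign is represented as a list of :class:`Batch` objects,
one per lot.  Each batch bundles the lot's sensor time series (lyophilization
signals LP1-LP7, sterile-filtration signals SF1-SF3) with the lot's
quality-database (QDB) record: single-point quality attributes plus the
absolute start/end timestamps of the processing steps.

All analysis downstream operates on relative time (seconds from the first
sample of a series); absolute timestamps live only in the QDB record and in
the optional ``start_timestamp`` anchor of a series, which is needed to cut
a continuous, unlabelled sensor stream into per-lot segments.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeries",
    "QDBRecord",
    "Batch",
    "StreamSegmentationReport",
]


@dataclass
class TimeSeries:
    """A single sensor trace.

    Parameters
    ----------
    signal_name : str
        Sensor identifier, e.g. ``"LP4"`` or ``"SF2"``.
    times : ndarray of float
        Seconds since the first sample, non-negative and strictly increasing.
    values : ndarray of float
        Measurements, same length as ``times``; all finite.
    unit : str
        Engineering unit of the values (``"°C"``, ``"bar"``, ``"kg"`` ...).
    lot_id : str, optional
        Lot the trace belongs to; ``None`` for un-contextualized streams.
    start_timestamp : datetime, optional
        Absolute wall-clock time of the first sample.  Only required when
        the series must be cut against absolute QDB intervals.
    """

    signal_name: str
    times: np.ndarray
    values: np.ndarray
    unit: str = ""
    lot_id: str | None = None
    start_timestamp: _dt.datetime | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if self.times.shape != self.values.shape:
            raise ValueError(
                f"times and values of {self.signal_name!r} differ in length "
                f"({self.times.size} vs {self.values.size})"
            )
        if self.times.size < 2:
            raise ValueError(f"series {self.signal_name!r} needs >= 2 samples")
        if not (np.isfinite(self.times).all() and np.isfinite(self.values).all()):
            raise ValueError(f"non-finite entries in series {self.signal_name!r}")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"times of {self.signal_name!r} are not strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        """Elapsed seconds between first and last sample."""
        return float(self.times[-1] - self.times[0])

    def median_dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    def slice(self, start: int, end: int) -> "TimeSeries":
        """Half-open index slice ``[start, end)`` as a new series (raw times kept)."""
        return TimeSeries(
            signal_name=self.signal_name,
            times=self.times[start:end].copy(),
            values=self.values[start:end].copy(),
            unit=self.unit,
            lot_id=self.lot_id,
            start_timestamp=self.start_timestamp,
        )

    def absolute_times(self) -> np.ndarray:
        """Sample timestamps as numpy ``datetime64[ns]`` (requires an anchor)."""
        if self.start_timestamp is None:
            raise ValueError(f"series {self.signal_name!r} has no absolute anchor")
        base = np.datetime64(self.start_timestamp, "ns")
        return base + (self.times * 1e9).astype("timedelta64[ns]")


@dataclass
class QDBRecord:
    """One lot's quality-database row.

    ``features`` maps feature name to a real value (``nan`` for missing);
    ``step_intervals`` maps a processing step (``"sterile_filtration"``,
    ``"lyophilization"``) to its absolute ``(start, end)`` interval.
    """

    lot_id: str
    features: dict[str, float] = field(default_factory=dict)
    step_intervals: dict[str, tuple[_dt.datetime, _dt.datetime]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for step, (start, end) in self.step_intervals.items():
            if not start < end:
                raise ValueError(
                    f"lot {self.lot_id!r}: step {step!r} interval end "
                    f"({end}) does not follow its start ({start})"
                )


@dataclass
class Batch:
    """A lot's aligned record: named time series plus the QDB row."""

    lot_id: str
    series: dict[str, TimeSeries] = field(default_factory=dict)
    qdb: QDBRecord | None = None

    def __post_init__(self) -> None:
        for name, ts in self.series.items():
            if ts.lot_id is not None and ts.lot_id != self.lot_id:
                raise ValueError(
                    f"series {name!r} carries lot {ts.lot_id!r} but batch is {self.lot_id!r}"
                )

    def add_series(self, ts: TimeSeries) -> None:
        if ts.lot_id is not None and ts.lot_id != self.lot_id:
            raise ValueError(
                f"series {ts.signal_name!r} carries lot {ts.lot_id!r} "
                f"but batch is {self.lot_id!r}"
            )
        if ts.signal_name in self.series:
            raise ValueError(f"duplicate signal {ts.signal_name!r} in batch {self.lot_id!r}")
        self.series[ts.signal_name] = ts

    @property
    def signal_names(self) -> list[str]:
        return sorted(self.series)


@dataclass
class StreamSegmentationReport:
    """Bookkeeping of how a continuous stream was attributed to lots."""

    total_samples: int
    assigned: dict[str, int] = field(default_factory=dict)
    coverage: dict[str, float] = field(default_factory=dict)
    unassigned_samples: int = 0
    short_lots: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if sum(self.assigned.values()) + self.unassigned_samples != self.total_samples:
            raise AssertionError("stream samples lost or duplicated during segmentation")
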