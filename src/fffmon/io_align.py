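"""Parsing and alignment of the three campaign data sources.

The three sources are (i) a quality-database (QDB) table with one row per
lot, (ii) per-lot lyophilization time-series tables, and (iii) a continuous,
month-spanning sterile-filtration stream that carries no lot labels and is
cut into per-lot segments using the filtration start/end timestamps stored
in the QDB.  Everything ends up contextualized into per-lot :class:`~fffmon.batch.Batch`
objects, the unit all later stages operate on.

Interval attribution is half-open, ``start <= t < end``, so adjacent lots can
never claim the same stream sample.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .batch import Batch, QDBRecord, StreamSegmentationReport, TimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "parse_qdb_table",
    "parse_timeseries_table",
    "segment_stream_by_intervals",
    "assemble_batches",
    "batches_to_long_frame",
    "write_batches",
    "write_qdb_table",
]

#: column-name convention for step timestamps in a QDB table
STEP_COLUMNS = {
    "sterile_filtration": ("sterile_filtration_start", "sterile_filtration_end"),
    "lyophilization": ("lyophilization_start", "lyophilization_end"),
}

#: ratio of max/median inter-sample gap above which a series is flagged irregular
IRREGULAR_GAP_RATIO = 10.0


def _parse_dt(value) -> _dt.datetime | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    ts = pd.Timestamp(value)
    if ts is pd.NaT:
        return None
    if ts.tzinfo is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    return ts.to_pydatetime()


def parse_qdb_table(table_source, *, delimiter: str = ",") -> list[QDBRecord]:
    """Read a QDB table into one :class:`QDBRecord` per row.

    The table must contain a ``lot_id`` column; columns named per
    :data:`STEP_COLUMNS` are parsed as ISO-8601 timestamps, every other
    column is treated as a numeric feature (non-numeric cells become NaN).
    Duplicate lot ids raise; a missing step timestamp is only warned about,
    because not every lot necessarily went through every step.
    """
    if isinstance(table_source, pd.DataFrame):
        df = table_source.copy()
    else:
        df = pd.read_csv(table_source, sep=delimiter, dtype=str)
    if "lot_id" not in df.columns:
        raise ValueError("QDB table lacks a 'lot_id' column")
    lots = df["lot_id"].astype(str)
    dup = lots[lots.duplicated()].unique()
    if dup.size:
        raise ValueError(f"duplicate lot_id in QDB table: {sorted(dup)}")

    ts_columns = {c for pair in STEP_COLUMNS.values() for c in pair}
    feature_cols = [c for c in df.columns if c != "lot_id" and c not in ts_columns]

    records: list[QDBRecord] = []
    for _, row in df.iterrows():
        lot = str(row["lot_id"])
        feats = {c: pd.to_numeric(pd.Series([row[c]]), errors="coerce").iloc[0] for c in feature_cols}
        feats = {k: float(v) if pd.notna(v) else float("nan") for k, v in feats.items()}
        intervals = {}
        for step, (c0, c1) in STEP_COLUMNS.items():
            if c0 not in df.columns or c1 not in df.columns:
                continue
            start, end = _parse_dt(row[c0]), _parse_dt(row[c1])
            if start is None or end is None:
                warnings.warn(f"lot {lot}: missing {step} timestamp(s); record retained")
                continue
            if not start < end:
                raise ValueError(f"lot {lot}: {step} interval end precedes start")
            intervals[step] = (start, end)
        records.append(QDBRecord(lot_id=lot, features=feats, step_intervals=intervals))
    return records


def parse_timeseries_table(
    table_source,
    layout: str = "long",
    *,
    delimiter: str = ",",
    units: dict[str, str] | None = None,
) -> tuple[list[TimeSeries], int]:
    """Read a delimited time-series table into :class:`TimeSeries` objects.

    ``layout="long"`` expects columns ``(lot_id?, timestamp, signal, value)``;
    ``layout="wide"`` expects ``timestamp`` plus one column per signal.
    Times are re-based to seconds from each series' first sample, with the
    absolute first timestamp kept as anchor.  Rows whose value does not parse
    as a number are dropped; the drop count is returned alongside.
    """
    units = units or {}
    if isinstance(table_source, pd.DataFrame):
        df = table_source.copy()
    else:
        df = pd.read_csv(table_source, sep=delimiter, dtype=str)

    if layout == "wide":
        if "timestamp" not in df.columns:
            raise ValueError("wide layout requires a 'timestamp' column")
        value_cols = [c for c in df.columns if c not in ("timestamp", "lot_id")]
        df = df.melt(
            id_vars=[c for c in ("lot_id", "timestamp") if c in df.columns],
            value_vars=value_cols,
            var_name="signal",
            value_name="value",
        )
    elif layout != "long":
        raise ValueError(f"unknown layout {layout!r}")

    required = {"timestamp", "signal", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"long layout requires columns {sorted(required)}")

    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    n_dropped = int(df["value"].isna().sum())
    df = df.dropna(subset=["value"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")

    keys = ["lot_id", "signal"] if "lot_id" in df.columns else ["signal"]
    out: list[TimeSeries] = []
    for key, grp in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        lot = str(key[0]) if "lot_id" in df.columns else None
        signal = str(key[-1])
        stamps = grp["timestamp"].to_numpy()
        if np.any(np.diff(stamps) <= np.timedelta64(0)):
            raise ValueError(f"non-monotone timestamps in series ({lot}, {signal})")
        secs = (stamps - stamps[0]) / np.timedelta64(1, "s")
        ts = TimeSeries(
            signal_name=signal,
            times=secs.astype(float),
            values=grp["value"].to_numpy(dtype=float),
            unit=units.get(signal, ""),
            lot_id=lot,
            start_timestamp=pd.Timestamp(stamps[0]).to_pydatetime(),
        )
        gaps = np.diff(ts.times)
        if gaps.size and np.max(gaps) > IRREGULAR_GAP_RATIO * np.median(gaps):
            warnings.warn(
                f"series ({lot}, {signal}): irregular sampling "
                f"(max/median gap ratio {np.max(gaps) / np.median(gaps):.1f})"
            )
        out.append(ts)
    return out, n_dropped


def segment_stream_by_intervals(
    stream: list[TimeSeries],
    records: list[QDBRecord],
    step_name: str = "sterile_filtration",
) -> tuple[dict[str, list[TimeSeries]], StreamSegmentationReport]:
    """Cut an unlabelled continuous stream into per-lot segments.

    Each lot receives the stream samples with ``start <= t < end`` of its QDB
    interval for ``step_name``, re-based to seconds from the interval start.
    Lots whose interval covers fewer than 2 samples are reported in
    ``report.short_lots`` rather than silently dropped.  Overlapping
    intervals are an error: a sample must belong to at most one lot.
    """
    intervals: list[tuple[str, _dt.datetime, _dt.datetime]] = []
    for rec in records:
        if step_name in rec.step_intervals:
            start, end = rec.step_intervals[step_name]
            intervals.append((rec.lot_id, start, end))
    intervals.sort(key=lambda x: x[1])
    for (lot_a, _, end_a), (lot_b, start_b, _) in zip(intervals, intervals[1:]):
        if start_b < end_a:
            raise ValueError(f"overlapping {step_name} intervals for lots {lot_a!r} and {lot_b!r}")

    total = sum(len(ts) for ts in stream)
    report = StreamSegmentationReport(total_samples=total)
    result: dict[str, list[TimeSeries]] = {lot: [] for lot, _, _ in intervals}
    assigned_counts = {lot: 0 for lot, _, _ in intervals}

    for ts in stream:
        abs_times = ts.absolute_times()
        claimed = np.zeros(len(ts), dtype=bool)
        for lot, start, end in intervals:
            lo = np.datetime64(start, "ns")
            hi = np.datetime64(end, "ns")
            mask = (abs_times >= lo) & (abs_times < hi)
            n = int(mask.sum())
            assigned_counts[lot] += n
            claimed |= mask
            if n < 2:
                continue
            sel = np.flatnonzero(mask)
            seg_times = (abs_times[sel] - lo) / np.timedelta64(1, "s")
            result[lot].append(
                TimeSeries(
                    signal_name=ts.signal_name,
                    times=seg_times.astype(float),
                    values=ts.values[sel].copy(),
                    unit=ts.unit,
                    lot_id=lot,
                    start_timestamp=start,
                )
            )
        report.unassigned_samples += int((~claimed).sum())

    n_signals = max(len(stream), 1)
    for lot, start, end in intervals:
        report.assigned[lot] = assigned_counts[lot]
        span = (end - start).total_seconds()
        # coverage: fraction of the interval carrying samples, from the median dt
        if stream and assigned_counts[lot] >= 2:
            dt = float(np.median([ts.median_dt() for ts in stream]))
            report.coverage[lot] = min(1.0, assigned_counts[lot] / n_signals * dt / span)
        else:
            report.coverage[lot] = 0.0
        if assigned_counts[lot] < 2 * n_signals:
            report.short_lots.append(lot)
            logger.warning("lot %s: %s interval covers < 2 samples per signal", lot, step_name)
    report.validate()
    return result, report


def assemble_batches(
    records: list[QDBRecord],
    lyo_series_by_lot: dict[str, list[TimeSeries]] | None = None,
    filtration_by_lot: dict[str, list[TimeSeries]] | None = None,
) -> list[Batch]:
    """Join the per-source data into one :class:`Batch` per QDB record.

    Missing sources leave a batch's series map partially filled (and logged);
    time series whose lot is absent from the QDB are excluded with a warning.
    """
    lyo_series_by_lot = lyo_series_by_lot or {}
    filtration_by_lot = filtration_by_lot or {}
    known = {rec.lot_id for rec in records}
    for source_name, source in (("lyophilization", lyo_series_by_lot), ("filtration", filtration_by_lot)):
        for lot in source:
            if lot not in known:
                warnings.warn(f"{source_name} series for unknown lot {lot!r} excluded")

    batches = []
    for rec in records:
        batch = Batch(lot_id=rec.lot_id, qdb=rec)
        for source in (lyo_series_by_lot, filtration_by_lot):
            for ts in source.get(rec.lot_id, []):
                ts.lot_id = rec.lot_id
                batch.add_series(ts)
        if not batch.series:
            logger.info("lot %s: no time-series source available", rec.lot_id)
        batches.append(batch)
    return batches


def batches_to_long_frame(batches: list[Batch]) -> pd.DataFrame:
    """Canonical long format: ``lot_id, signal, t_seconds, value, unit``."""
    parts = []
    for batch in batches:
        for name in sorted(batch.series):
            ts = batch.series[name]
            parts.append(
                pd.DataFrame(
                    {
                        "lot_id": batch.lot_id,
                        "signal": name,
                        "t_seconds": ts.times,
                        "value": ts.values,
                        "unit": ts.unit,
                    }
                )
            )
    if not parts:
        return pd.DataFrame(columns=["lot_id", "signal", "t_seconds", "value", "unit"])
    return pd.concat(parts, ignore_index=True)


def write_batches(batches: list[Batch], outdir: str | Path) -> Path:
    """Write the long-format CSV plus a JSON manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    batches_to_long_frame(batches).to_csv(outdir / "batches_long.csv", index=False)
    manifest = {
        "n_batches": len(batches),
        "lots": [
            {
                "lot_id": b.lot_id,
                "signals": b.signal_names,
                "n_qdb_features": len(b.qdb.features) if b.qdb else 0,
            }
            for b in batches
        ],
    }
    path = outdir / "batch_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def write_qdb_table(records: list[QDBRecord], path: str | Path, *, delimiter: str = ",") -> None:
    """Serialize QDB records back to the tabular on-disk form (round-trippable)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"lot_id": rec.lot_id}
        row.update({k: repr(v) if np.isfinite(v) else "" for k, v in rec.features.items()})
        for step, (c0, c1) in STEP_COLUMNS.items():
            if step in rec.step_intervals:
                start, end = rec.step_intervals[step]
                row[c0] = start.isoformat()
                row[c1] = end.isoformat()
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
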