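"""Per-phase feature extraction and assembly of the lot x feature matrix.

From every phase of every signal, summary statistics are pulled: mean,
minimum and maximum for any phase; the sample standard deviation for
plateaus (a noise fingerprint); the root-mean-square residual of a
least-squares line for slopes (ramp-shape fidelity); and the duration in
seconds.  Canonical column names are ``<signal>|<phase>|<statistic>``.
Extracted columns are concatenated with the lot's quality-database features,
zero-variance columns are dropped, and the remaining columns are scaled to
a common location/spread so that the multivariate model weighs every
feature equally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .batch import Batch, TimeSeries
from .cleaning import MAD_SCALE
from .phase_step import Phase, Segmentation

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "extract_phase_features",
    "specs_from_segmentations",
    "build_feature_matrix",
    "drop_zero_variance",
    "scale_features",
    "impute_missing",
]

STATISTICS = ("mean", "min", "max", "plateau_std", "slope_residual_rmse", "duration_seconds")


@dataclass(frozen=True)
class FeatureSpec:
    """One requested statistic of one phase of one signal."""

    signal_name: str
    phase_label: str
    statistic: str

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")

    @property
    def column(self) -> str:
        return f"{self.signal_name}|{self.phase_label}|{self.statistic}"


@dataclass
class FeatureMatrix:
    """Lots x features with per-column provenance.

    ``values`` is a DataFrame indexed by lot id; ``provenance`` maps each
    column to ``"extracted"`` or ``"qdb"``.  NaN marks a missing entry.
    """

    values: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature columns: {dupes}")
        missing = [c for c in self.values.columns if c not in self.provenance]
        for c in missing:
            self.provenance[c] = "extracted"

    @property
    def lot_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def _phase_stat(ts: TimeSeries, phase: Phase, statistic: str) -> float:
    seg_t = ts.times[phase.start_index : phase.end_index]
    seg_y = ts.values[phase.start_index : phase.end_index]
    if statistic == "duration_seconds":
        return float(phase.duration)
    if seg_y.size < 2:
        raise ValueError("phase carries < 2 samples")
    if statistic == "mean":
        return float(np.mean(seg_y))
    if statistic == "min":
        return float(np.min(seg_y))
    if statistic == "max":
        return float(np.max(seg_y))
    if statistic == "plateau_std":
        return float(np.std(seg_y, ddof=1))
    if statistic == "slope_residual_rmse":
        coeffs = np.polyfit(seg_t, seg_y, 1)
        resid = seg_y - np.polyval(coeffs, seg_t)
        return float(np.sqrt(np.mean(resid**2)))
    raise ValueError(f"unknown statistic {statistic!r}")


def extract_phase_features(
    ts: TimeSeries, phases: list[Phase], specs: list[FeatureSpec]
) -> dict[str, float]:
    """Evaluate the specs that target this signal; missing phases yield NaN."""
    by_label = {p.label: p for p in phases}
    out: dict[str, float] = {}
    for spec in specs:
        if spec.signal_name != ts.signal_name:
            continue
        phase = by_label.get(spec.phase_label)
        if phase is None:
            logger.info("%s: phase %r absent, feature %s missing", ts.signal_name, spec.phase_label, spec.column)
            out[spec.column] = float("nan")
            continue
        if spec.statistic == "plateau_std" and phase.kind == "slope":
            raise ValueError(f"plateau_std requested on slope phase {phase.label!r}")
        if spec.statistic == "slope_residual_rmse" and phase.kind == "plateau":
            raise ValueError(f"slope_residual_rmse requested on plateau phase {phase.label!r}")
        try:
            out[spec.column] = _phase_stat(ts, phase, spec.statistic)
        except ValueError:
            logger.info("%s: phase %r too short, feature %s missing", ts.signal_name, phase.label, spec.column)
            out[spec.column] = float("nan")
    return out


def specs_from_segmentations(
    segmentations: dict[str, dict[str, Segmentation]],
    rule_phases: dict[str, list[Phase]] | None = None,
) -> list[FeatureSpec]:
    """Derive a consistent spec list from observed phases across all lots.

    Step phases get mean/min/max plus the kind-specific spread statistic;
    rule phases additionally get their duration.  The union over lots is
    taken so that a lot missing a phase simply yields missing values.
    """
    step_kinds: dict[tuple[str, str], str] = {}
    for per_signal in segmentations.values():
        for signal, seg in per_signal.items():
            for phase in seg.phases:
                step_kinds[(signal, phase.label)] = phase.kind
    specs: list[FeatureSpec] = []
    for (signal, label), kind in sorted(step_kinds.items()):
        spread = "plateau_std" if kind == "plateau" else "slope_residual_rmse"
        for stat in ("mean", "min", "max", spread):
            specs.append(FeatureSpec(signal, label, stat))

    specs_rule: set[FeatureSpec] = set()
    for phases in (rule_phases or {}).values():
        for phase in phases:
            signal = phase.signal_name or "LP4"
            for stat in ("mean", "min", "max", "duration_seconds"):
                specs_rule.add(FeatureSpec(signal, phase.label, stat))
    specs.extend(sorted(specs_rule, key=lambda s: (s.signal_name, s.phase_label, s.statistic)))
    return specs


def build_feature_matrix(
    batches: list[Batch],
    segmentations: dict[str, dict[str, Segmentation]],
    rule_phases: dict[str, list[Phase]] | None = None,
    specs: list[FeatureSpec] | None = None,
) -> FeatureMatrix:
    """One row per batch: extracted features then QDB features.

    Extracted columns are ordered by (signal, phase, statistic); QDB columns
    keep their table order.  Row values are bound to the lot id, so shuffling
    the batch input order only permutes rows.
    """
    rule_phases = rule_phases or {}
    if specs is None:
        specs = specs_from_segmentations(segmentations, rule_phases)
    specs = sorted(set(specs), key=lambda s: (s.signal_name, s.phase_label, s.statistic))

    rows: dict[str, dict[str, float]] = {}
    for batch in batches:
        row: dict[str, float] = {spec.column: float("nan") for spec in specs}
        lot_segs = segmentations.get(batch.lot_id, {})
        lot_rules = rule_phases.get(batch.lot_id, [])
        for signal, ts in batch.series.items():
            phases: list[Phase] = []
            if signal in lot_segs:
                phases.extend(lot_segs[signal].phases)
            phases.extend([p for p in lot_rules if _rule_targets(p, signal)])
            if phases:
                row.update(extract_phase_features(ts, phases, specs))
            # whole-signal statistics: specs whose phase label is "__all__"
            whole = [s for s in specs if s.signal_name == signal and s.phase_label == "__all__"]
            if whole:
                full = Phase("__all__", "rule", 0, len(ts), float(ts.times[0]), float(ts.times[-1]))
                row.update(extract_phase_features(ts, [full], whole))
        rows[batch.lot_id] = row

    extracted = pd.DataFrame.from_dict(rows, orient="index")
    extracted = extracted[[spec.column for spec in specs]]
    extracted.index.name = "lot_id"

    qdb_cols: list[str] = []
    for batch in batches:
        if batch.qdb:
            for name in batch.qdb.features:
                if name not in qdb_cols:
                    qdb_cols.append(name)
    qdb = pd.DataFrame.from_dict(
        {
            b.lot_id: {c: (b.qdb.features.get(c, float("nan")) if b.qdb else float("nan")) for c in qdb_cols}
            for b in batches
        },
        orient="index",
    )
    if qdb_cols:
        qdb = qdb[qdb_cols]

    clash = set(extracted.columns) & set(qdb.columns)
    if clash:
        raise ValueError(f"QDB feature names collide with extracted columns: {sorted(clash)}")
    values = pd.concat([extracted, qdb], axis=1)
    values = values.loc[[b.lot_id for b in batches]]
    provenance = {c: "extracted" for c in extracted.columns}
    provenance.update({c: "qdb" for c in qdb.columns})
    return FeatureMatrix(values=values, provenance=provenance)


def _rule_targets(phase: Phase, signal: str) -> bool:
    return phase.kind == "rule" and (phase.signal_name or "LP4") == signal


def drop_zero_variance(fm: FeatureMatrix) -> tuple[FeatureMatrix, list[str]]:
    """Remove columns whose non-missing values are all equal (or all missing)."""
    removed: list[str] = []
    for col in fm.values.columns:
        vals = fm.values[col].dropna()
        if vals.empty or bool((vals == vals.iloc[0]).all()):
            removed.append(col)
    kept = [c for c in fm.values.columns if c not in removed]
    if not kept:
        raise ValueError("zero-variance filter removed every column")
    if removed:
        logger.info("zero-variance filter removed %d columns", len(removed))
    out = FeatureMatrix(
        values=fm.values[kept].copy(),
        provenance={c: fm.provenance[c] for c in kept},
    )
    return out, removed


def scale_features(
    fm: FeatureMatrix, method: str = "robust"
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Column-wise location/scale normalization.

    ``robust`` centers on the median and scales by the (Gaussian-consistent)
    MAD so that the scaling itself cannot be dragged by an outlying lot;
    ``classical`` uses mean and standard deviation.  A column whose MAD is
    zero falls back to classical scaling (logged).  Returns the scaled matrix
    and a frame of the applied (center, scale) per column, with which
    ``unscale`` is exact.
    """
    if method not in ("robust", "classical"):
        raise ValueError(f"unknown scaling method {method!r}")
    centers, scales = {}, {}
    for col in fm.values.columns:
        vals = fm.values[col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"column {col!r} has no observed values")
        if method == "robust":
            center = float(np.median(vals))
            scale = MAD_SCALE * float(np.median(np.abs(vals - center)))
            if scale == 0:
                logger.info("column %r: MAD is zero, classical fallback", col)
                center = float(np.mean(vals))
                scale = float(np.std(vals, ddof=1))
        else:
            center = float(np.mean(vals))
            scale = float(np.std(vals, ddof=1))
        if scale == 0:
            raise ValueError(f"column {col!r} has zero spread; run drop_zero_variance first")
        centers[col], scales[col] = center, scale
    params = pd.DataFrame({"center": centers, "scale": scales})
    scaled = (fm.values - params["center"]) / params["scale"]
    return FeatureMatrix(values=scaled, provenance=dict(fm.provenance)), params


def impute_missing(
    fm: FeatureMatrix, max_missing_fraction: float = 0.2
) -> tuple[FeatureMatrix, list[str]]:
    """Median-impute sporadic gaps; drop columns missing in too many lots."""
    dropped = [
        c for c in fm.values.columns
        if fm.values[c].isna().mean() > max_missing_fraction
    ]
    if dropped:
        logger.warning("dropping %d columns with > %.0f%% missing entries", len(dropped), 100 * max_missing_fraction)
    kept = [c for c in fm.values.columns if c not in dropped]
    if not kept:
        raise ValueError("all columns exceeded the missingness limit")
    values = fm.values[kept].copy()
    values = values.fillna(values.median())
    return FeatureMatrix(values=values, provenance={c: fm.provenance[c] for c in kept}), dropped
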