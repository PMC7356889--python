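"""Segmentation of step-shaped signals into alternating plateaus and slopes.

Process signals in formulation/fill/finish equipment are largely piecewise
constant: setpoint changes produce sharp ramps between long plateaus.  A
slope is declared open at the first sample ``t`` where the lookahead
difference ``|y_t - y_{t+i}|`` exceeds a threshold and closed at the first
later sample where it falls back to or below the threshold; everything
between slopes is a plateau.

The threshold is adaptive: each candidate segmentation is validated against
expert-supplied duration bounds per phase kind, a too-short phase raises the
threshold, a too-long phase lowers it, and the scan restarts from scratch,
up to ``max_iterations`` times.  If no iteration satisfies every bound, the
iteration with the fewest violations is returned flagged as non-converged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .batch import TimeSeries
from .cleaning import estimate_noise_sigma

logger = logging.getLogger(__name__)

__all__ = ["Phase", "StepConfig", "Segmentation", "detect_step_phases", "classify_segment"]


@dataclass
class Phase:
    """A labeled half-open interval ``[start_index, end_index)`` of one signal."""

    label: str
    kind: str  # slope | plateau | rule
    start_index: int
    end_index: int
    start_time: float
    end_time: float
    signal_name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("slope", "plateau", "rule"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if not self.start_index < self.end_index:
            raise ValueError(
                f"phase {self.label!r}: empty index interval "
                f"[{self.start_index}, {self.end_index})"
            )

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class StepConfig:
    """Tunables of the step-signal detector.

    ``lookahead`` is the sample offset ``i`` of the difference test;
    ``threshold0`` the initial threshold in value units (``None`` derives
    3 x the series' noise sigma); ``duration_bounds`` maps a phase kind to
    its admissible (min_seconds, max_seconds).
    """

    lookahead: int = 1
    threshold0: float | None = None
    duration_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    threshold_step: float = 1.5
    max_iterations: int = 20

    def __post_init__(self) -> None:
        if self.lookahead < 1:
            raise ValueError("lookahead must be >= 1")
        if self.threshold_step <= 1:
            raise ValueError("threshold_step must exceed 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        for kind, (lo, hi) in self.duration_bounds.items():
            if not lo < hi:
                raise ValueError(f"duration bound for {kind!r} has min >= max")


@dataclass
class Segmentation:
    signal_name: str
    phases: list[Phase]
    final_threshold: float
    iterations_used: int
    converged: bool = True
    leading_slope: bool = False

    def __post_init__(self) -> None:
        for a, b in zip(self.phases, self.phases[1:]):
            if a.end_index != b.start_index:
                raise ValueError("phases must tile the analyzed region without gaps")
            if a.kind == b.kind:
                raise ValueError("consecutive phases must alternate kinds")

    def phase(self, label: str) -> Phase:
        for p in self.phases:
            if p.label == label:
                return p
        raise KeyError(label)


def _scan(values: np.ndarray, i: int, threshold: float) -> list[tuple[int, int, str]]:
    """One left-to-right pass; returns (start, end, kind) index intervals.

    The lookahead difference at ``t`` compares ``y_t`` with ``y_{t+i}``, so an
    exceedance at ``t`` means the level changes *after* ``t``: the slope is
    taken to begin at ``t+1`` (at ``t`` itself when the series opens mid-slope)
    and to end after the first ``t`` at which the difference has settled.
    """
    n = values.size
    d = np.abs(values[:-i] - values[i:]) > threshold  # length n - i
    segments: list[tuple[int, int, str]] = []
    pos = 0
    in_slope = bool(d[0])
    t = 0
    while t < d.size:
        if not in_slope:
            if d[t]:
                boundary = min(t + 1, n - 1)
                if boundary > pos:
                    segments.append((pos, boundary, "plateau"))
                pos = boundary
                in_slope = True
            t += 1
        else:
            if not d[t]:
                boundary = min(t + 1, n)
                segments.append((pos, boundary, "slope"))
                pos = boundary
                in_slope = False
            t += 1
    if pos < n:
        segments.append((pos, n, "slope" if in_slope else "plateau"))
    return segments


def _count_violations(
    segments: list[tuple[int, int, str]],
    times: np.ndarray,
    bounds: dict[str, tuple[float, float]],
) -> tuple[int, int]:
    """Returns (#violations, first violation sign: +1 too short, -1 too long, 0 none)."""
    n_viol, first_sign = 0, 0
    for start, end, kind in segments:
        if kind not in bounds:
            continue
        lo, hi = bounds[kind]
        dur = times[min(end, times.size - 1)] - times[start]
        sign = 0
        if dur < lo:
            sign = +1
        elif dur > hi:
            sign = -1
        if sign:
            n_viol += 1
            if first_sign == 0:
                first_sign = sign
    return n_viol, first_sign


def detect_step_phases(ts: TimeSeries, cfg: StepConfig | None = None) -> Segmentation:
    """Adaptive-threshold segmentation of a step signal.

    Deterministic for identical input and config.  Scale-equivariant: scaling
    values and threshold by the same constant leaves boundaries unchanged.
    """
    cfg = cfg or StepConfig()
    i = cfg.lookahead
    n = len(ts)
    if n <= 2 * i:
        raise ValueError(f"series length {n} too short for lookahead {i} (need > {2 * i})")

    threshold = cfg.threshold0
    if threshold is None:
        threshold = 3.0 * estimate_noise_sigma(ts)
        if threshold == 0:
            threshold = np.finfo(float).tiny

    best: tuple[int, list[tuple[int, int, str]], float, int] | None = None
    iterations = 0
    for iterations in range(1, cfg.max_iterations + 1):
        segments = _scan(ts.values, i, threshold)
        n_viol, sign = _count_violations(segments, ts.times, cfg.duration_bounds)
        if best is None or n_viol < best[0]:
            best = (n_viol, segments, threshold, iterations)
        if n_viol == 0:
            break
        # Fig.-style feedback: a premature phase end raises the threshold,
        # an overlong phase lowers it, and the scan restarts globally.
        threshold = threshold * cfg.threshold_step if sign > 0 else threshold / cfg.threshold_step

    assert best is not None
    n_viol, segments, used_threshold, used_iter = best
    converged = n_viol == 0
    if not converged:
        logger.warning(
            "%s: step segmentation did not converge (%d duration violations after %d iterations)",
            ts.signal_name, n_viol, iterations,
        )

    counters = {"plateau": 0, "slope": 0}
    phases = []
    for start, end, kind in segments:
        counters[kind] += 1
        phases.append(
            Phase(
                label=f"{kind}{counters[kind]:02d}",
                kind=kind,
                start_index=start,
                end_index=end,
                start_time=float(ts.times[start]),
                end_time=float(ts.times[min(end, n - 1)]),
            )
        )
    leading_slope = bool(phases and phases[0].kind == "slope")
    if leading_slope:
        logger.warning("%s: signal begins mid-slope", ts.signal_name)
    return Segmentation(
        signal_name=ts.signal_name,
        phases=phases,
        final_threshold=float(used_threshold),
        iterations_used=used_iter,
        converged=converged,
        leading_slope=leading_slope,
    )


def classify_segment(ts: TimeSeries, start: int, end: int, threshold: float, i: int = 1) -> str:
    """Label an index interval ``[start, end)`` as slope or plateau.

    Uses the median lookahead difference so isolated noisy samples cannot
    flip the call.
    """
    if end - start < 2:
        raise ValueError("segment needs >= 2 samples")
    seg = ts.values[start:end]
    if seg.size <= i:
        d = np.abs(np.diff(seg))
    else:
        d = np.abs(seg[:-i] - seg[i:])
    return "slope" if float(np.median(d)) > threshold else "plateau"
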