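"""Sensor-artifact removal for the sterile-filtration signals.

Two artifact classes are handled, both process-typical but irrelevant (and
harmful) for multivariate analysis:

* the sharp pressure peak at the very end of a filtration run (signal SF2) —
  removed by truncating the terminal high-slope suffix;
* short, tall excursions on the product-weight signal SF3 caused by
  operators stepping on the scale — removed by deleting every sample of an
  excursion whose local slope magnitude exceeds a threshold, until the
  signal returns to its pre-excursion level.

Samples are deleted, never interpolated: cleaning must not fabricate data,
and all downstream phase/feature code tolerates non-uniform time grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .batch import TimeSeries

__all__ = [
    "CleaningConfig",
    "CleaningReport",
    "estimate_noise_sigma",
    "default_spike_slope_threshold",
    "remove_terminal_slope",
    "remove_spikes",
]

#: consistency factor making the MAD unbiased for a Gaussian scale
MAD_SCALE = 1.4826


@dataclass
class CleaningConfig:
    """Thresholds for the two cleaners.

    ``spike_slope_threshold`` and ``terminal_slope_threshold`` are in value
    units per second; ``spike_max_duration`` caps how long an excursion may
    last (seconds) before deletion stops regardless of recovery.
    """

    spike_slope_threshold: float | None = None
    spike_max_duration: float = 600.0
    terminal_slope_threshold: float | None = None
    noise_sigma_estimator: str = "mad_of_differences"

    def __post_init__(self) -> None:
        for name in ("spike_slope_threshold", "terminal_slope_threshold"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spike_max_duration <= 0:
            raise ValueError("spike_max_duration must be positive")
        if self.noise_sigma_estimator not in ("mad_of_differences", "std_of_differences"):
            raise ValueError(f"unknown estimator {self.noise_sigma_estimator!r}")


@dataclass
class CleaningReport:
    samples_removed: int = 0
    regions: list[tuple[float, float, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "samples_removed": self.samples_removed,
            "regions": [
                {"start_time": s, "end_time": e, "reason": r} for s, e, r in self.regions
            ],
        }


def estimate_noise_sigma(ts: TimeSeries, estimator: str = "mad_of_differences") -> float:
    """Noise standard deviation from first differences.

    For i.i.d. noise the difference of neighbours has variance ``2*sigma^2``,
    hence the division by sqrt(2).  The MAD variant ignores the few large
    differences contributed by ramps or spikes, so it remains calibrated on
    step-shaped signals as long as ramp samples are a small minority.
    """
    if len(ts) < 3:
        raise ValueError("need >= 3 samples to estimate noise")
    d = np.diff(ts.values)
    if estimator == "mad_of_differences":
        scale = MAD_SCALE * float(np.median(np.abs(d - np.median(d))))
    elif estimator == "std_of_differences":
        scale = float(np.std(d, ddof=1))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return scale / np.sqrt(2.0)


def default_spike_slope_threshold(ts: TimeSeries, estimator: str = "mad_of_differences") -> float:
    """10 x noise sigma per median sampling interval.

    The drained-weight signal has a very low true slope, so anything an order
    of magnitude above the noise-implied slope is an interference.
    """
    sigma = estimate_noise_sigma(ts, estimator)
    dt = ts.median_dt()
    thr = 10.0 * sigma / dt
    if thr <= 0:
        # constant series: any excursion at all is a spike
        thr = np.finfo(float).tiny
    return thr


def _local_slopes(ts: TimeSeries) -> np.ndarray:
    """Centered-difference slope over a 3-sample window (one-sided at the ends).

    Using a window rather than single-sample differences keeps one noisy
    sample from triggering the detectors.
    """
    t, y = ts.times, ts.values
    slopes = np.empty_like(y)
    slopes[1:-1] = (y[2:] - y[:-2]) / (t[2:] - t[:-2])
    slopes[0] = (y[1] - y[0]) / (t[1] - t[0])
    slopes[-1] = (y[-1] - y[-2]) / (t[-1] - t[-2])
    return slopes


def remove_terminal_slope(
    ts: TimeSeries, cfg: CleaningConfig | None = None
) -> tuple[TimeSeries, CleaningReport]:
    """Truncate the terminal high-slope suffix (end-of-run pressure peak).

    Scans backward from the last sample while the local slope magnitude
    exceeds ``terminal_slope_threshold`` and truncates from the start of that
    maximal suffix.  Interior slopes are never touched; if the series does
    not end on a high slope it is returned unchanged.
    """
    cfg = cfg or CleaningConfig()
    thr = cfg.terminal_slope_threshold
    if thr is None:
        thr = default_spike_slope_threshold(ts, cfg.noise_sigma_estimator)
    # backward differences localize the peak onset to the sample, unlike the
    # centered window whose support leaks one sample into the flat prefix
    slopes = np.empty(len(ts))
    slopes[1:] = np.abs(np.diff(ts.values) / np.diff(ts.times))
    slopes[0] = slopes[1]
    n = len(ts)
    # the suffix ends at the last *sustained* low-slope run (3 samples), so a
    # single noisy dip inside the terminal ramp cannot end the scan early
    low = slopes <= thr
    run = 3 if n >= 3 else 1
    sustained = np.flatnonzero(
        np.convolve(low.astype(int), np.ones(run, dtype=int), mode="valid") == run
    )
    report = CleaningReport()
    if sustained.size and sustained[-1] + run == n:
        return ts, report  # series ends on a settled stretch: nothing terminal
    j = int(sustained[-1] + run) if sustained.size else 0
    if j < 2:
        raise ValueError("terminal-slope truncation would leave < 2 samples")
    report.samples_removed = n - j
    report.regions.append((float(ts.times[j]), float(ts.times[n - 1]), "terminal_slope"))
    return ts.slice(0, j), report


def remove_spikes(
    ts: TimeSeries, cfg: CleaningConfig | None = None
) -> tuple[TimeSeries, CleaningReport]:
    """Delete operator-induced excursions from a slowly varying signal.

    An excursion starts where the local slope magnitude exceeds
    ``spike_slope_threshold``; every sample from there on is deleted until
    the value returns within ``3*sigma`` of the level just before the
    excursion, or ``spike_max_duration`` seconds have elapsed.  The cleaned
    series is a subsequence of the input.
    """
    cfg = cfg or CleaningConfig()
    thr = cfg.spike_slope_threshold
    if thr is None:
        thr = default_spike_slope_threshold(ts, cfg.noise_sigma_estimator)
    sigma = estimate_noise_sigma(ts, cfg.noise_sigma_estimator)
    band = 3.0 * sigma if sigma > 0 else 0.0

    t, y = ts.times, ts.values
    slopes = np.abs(_local_slopes(ts))
    n = len(ts)
    keep = np.ones(n, dtype=bool)
    report = CleaningReport()

    idx = 1  # sample 0 anchors the baseline
    while idx < n:
        if slopes[idx] <= thr:
            idx += 1
            continue
        baseline = y[np.flatnonzero(keep[:idx])[-1]]
        # the centered window also elevates the slope of the clean neighbours;
        # the excursion proper starts at the first sample leaving the noise band
        start = idx
        while start < min(idx + 3, n) and abs(y[start] - baseline) <= band:
            start += 1
        if start == min(idx + 3, n) and (start == n or abs(y[start] - baseline) <= band):
            idx += 1  # slope trigger without a value excursion: leave intact
            continue
        end = start
        while end < n and t[end] - t[start] <= cfg.spike_max_duration and abs(y[end] - baseline) > band:
            end += 1
        keep[start:end] = False
        report.regions.append((float(t[start]), float(t[min(end, n - 1)]), "spike"))
        idx = end + 1

    removed = int((~keep).sum())
    if removed > 0.5 * n:
        raise ValueError(
            f"spike removal would delete {removed}/{n} samples; "
            "spike_slope_threshold is likely misconfigured"
        )
    report.samples_removed = removed
    if removed == 0:
        report.regions.clear()
        return ts, report
    kept = np.flatnonzero(keep)
    out = TimeSeries(
        signal_name=ts.signal_name,
        times=t[kept].copy(),
        values=y[kept].copy(),
        unit=ts.unit,
        lot_id=ts.lot_id,
        start_timestamp=ts.start_timestamp,
    )
    return out, report
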