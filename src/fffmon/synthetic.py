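"""Synthetic formulation/fill/finish campaigns with known ground truth.

Real campaign data of this kind is proprietary, so every stage of the
package is exercised against a generator that emulates the statistical
shape of such a campaign: step-profile time series (plateaus joined by
sharp ramps) with Gaussian sensor noise, a terminal pressure peak on SF2,
operator-induced weight spikes on SF3, a continuous absolutely-timestamped
sterile-filtration stream cut apart by quality-database (QDB) timestamps,
correlated QDB features, and planted abnormal lots (inflated sensor noise,
shifted plateau levels, shifted QDB values).

Everything is derived deterministically from one master seed, and the
returned :class:`GroundTruth` retains the true phase boundaries, spike
positions, clean signals and contamination labels, so recovery rates can be
measured exactly.

The default campaign mirrors the shape of a mid-size commercial campaign:
58 lots, 10 signals (LP1-LP7, SF1-SF3), 122 QDB features of which a handful
are constant, and phase/feature definitions that yield 130 extracted
features per lot.  No lyophilization physics is modelled — only the
statistical shape that the monitoring workflow consumes.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .batch import Batch, QDBRecord, TimeSeries
from .features import FeatureSpec
from .phase_rules import default_lp_ruleset, evaluate_predicate
from .phase_step import StepConfig

__all__ = [
    "StepProfile",
    "Contamination",
    "CampaignSpec",
    "GroundTruth",
    "generate_campaign",
    "generate_noise_study",
    "default_feature_specs",
    "default_step_config",
]

LP_DT = 60.0  # lyophilization sampling period, seconds
SF_DT = 30.0  # sterile-filtration sampling period, seconds
SF_SPAN = 7200.0  # filtration duration per lot, seconds
SF_GAP = 3600.0  # idle gap between consecutive lots in the stream, seconds


@dataclass(frozen=True)
class StepProfile:
    """A step-signal template: plateau (level, duration) pairs joined by ramps."""

    plateaus: tuple[tuple[float, float], ...]
    ramps: tuple[float, ...] = ()
    sigma: float = 0.0  # sensor noise standard deviation, value units
    unit: str = ""

    def __post_init__(self) -> None:
        if len(self.ramps) != len(self.plateaus) - 1:
            raise ValueError("need exactly one ramp between consecutive plateaus")

    def breakpoints(self) -> list[tuple[float, float, str]]:
        """(start_time, end_time, kind) of every plateau/ramp segment."""
        out = []
        t = 0.0
        for idx, (level, dur) in enumerate(self.plateaus):
            out.append((t, t + dur, "plateau"))
            t += dur
            if idx < len(self.ramps):
                out.append((t, t + self.ramps[idx], "slope"))
                t += self.ramps[idx]
        return out

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.plateaus) + sum(self.ramps)

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        """Noise-free piecewise-linear template values."""
        knots_t, knots_y = [0.0], [self.plateaus[0][0]]
        t = 0.0
        for idx, (level, dur) in enumerate(self.plateaus):
            if idx > 0:
                knots_t.append(t)
                knots_y.append(level)
            t += dur
            knots_t.append(t)
            knots_y.append(level)
            if idx < len(self.ramps):
                t += self.ramps[idx]
        return np.interp(times, knots_t, knots_y)


# --- default signal roster -------------------------------------------------
# Levels/durations are chosen so that (a) every ramp increment per sample is
# at least ~10x the sensor noise, keeping the step detector's operating
# point realistic; (b) the LP3/LP4 relative difference first drops below 20%
# at a unique time on LP4's evacuation ramp; (c) LP4's value at that moment
# is far enough from its holding plateau that the "vacuum returns to its
# earlier value" condition cannot trigger prematurely; (d) LP1's first
# increasing ramp (shelf heating) falls strictly between those two events.

def _default_lp_profiles() -> dict[str, StepProfile]:
    return {
        "LP1": StepProfile(  # inlet temperature, °C
            plateaus=((20.0, 1800.0), (-40.0, 9000.0), (-5.0, 6600.0), (25.0, 9000.0)),
            ramps=(1200.0, 1200.0, 1200.0),
            sigma=0.10, unit="°C",
        ),
        "LP2": StepProfile(  # outlet temperature, °C
            plateaus=((20.0, 1800.0), (-45.0, 10200.0), (-20.0, 6600.0), (-5.0, 9000.0)),
            ramps=(1200.0, 600.0, 600.0),
            sigma=0.10, unit="°C",
        ),
        "LP3": StepProfile(  # chamber vacuum 1, bar
            plateaus=((0.20, 30000.0),),
            sigma=0.0005, unit="bar",
        ),
        "LP4": StepProfile(  # chamber vacuum 2, bar
            plateaus=((1.0, 3000.0), (0.10, 16800.0), (1.0, 3000.0)),
            ramps=(3600.0, 3600.0),
            sigma=0.0005, unit="bar",
        ),
        "LP5": StepProfile(  # liquid-nitrogen temperature, °C
            plateaus=((-180.0, 6000.0), (-196.0, 12000.0), (-188.0, 11100.0)),
            ramps=(600.0, 300.0),
            sigma=0.05, unit="°C",
        ),
        "LP6": StepProfile(  # condenser pressure, bar
            plateaus=((1.0, 9000.0), (0.5, 20700.0)),
            ramps=(300.0,),
            sigma=0.005, unit="bar",
        ),
        "LP7": StepProfile(  # condenser vacuum, bar
            plateaus=((0.8, 6000.0), (0.05, 23400.0)),
            ramps=(600.0,),
            sigma=0.002, unit="bar",
        ),
    }


def _default_sf_profiles() -> dict[str, StepProfile]:
    return {
        "SF1": StepProfile(plateaus=((8.0, SF_SPAN),), sigma=0.05, unit="°C"),
        # plateau plus the end-of-filtration pressure peak (to be truncated)
        "SF2": StepProfile(
            plateaus=((1.2, 6600.0), (2.4, 0.0)), ramps=(600.0,), sigma=0.01, unit="bar"
        ),
        # slow product drain; spikes are injected on top
        "SF3": StepProfile(
            plateaus=((500.0, 0.0), (497.0, 0.0)), ramps=(SF_SPAN,), sigma=0.05, unit="kg"
        ),
    }


@dataclass
class Contamination:
    """One planted abnormal lot.

    ``mechanism`` is one of ``noise_inflation`` (sensor noise of ``signal``
    multiplied by ``factor``), ``plateau_shift`` (``delta`` added to plateau
    ``plateau_index`` of ``signal``), or ``qdb_shift`` (``n_features`` QDB
    columns shifted by ``delta`` column standard deviations).
    """

    lot_index: int
    mechanism: str
    signal: str = "LP2"
    factor: float = 1.3
    delta: float = 3.0
    plateau_index: int = 2
    n_features: int = 3

    def __post_init__(self) -> None:
        if self.mechanism not in ("noise_inflation", "plateau_shift", "qdb_shift"):
            raise ValueError(f"unknown contamination mechanism {self.mechanism!r}")


@dataclass
class CampaignSpec:
    """Everything the generator needs; defaults emulate a 58-lot campaign."""

    n_lots: int = 58
    lp_profiles: dict[str, StepProfile] = field(default_factory=_default_lp_profiles)
    sf_profiles: dict[str, StepProfile] = field(default_factory=_default_sf_profiles)
    n_qdb_features: int = 122
    n_qdb_constant: int = 5
    n_qdb_factors: int = 5
    spikes_per_lot: int = 2
    spike_magnitude: float = 80.0  # kg: an operator on the scale
    spike_duration: float = 120.0  # seconds
    level_jitter: float = 0.01  # lot-to-lot relative plateau-level jitter
    duration_jitter: float = 0.03  # lot-to-lot relative duration jitter
    noise_jitter: float = 0.03  # lot-to-lot relative noise-level jitter
    noise_scale: float = 1.0  # global multiplier on all sensor noise
    contaminations: list[Contamination] = field(default_factory=list)
    start: _dt.datetime = _dt.datetime(2019, 1, 7, 6, 0, 0)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lots < 4:
            raise ValueError("n_lots must be >= 4")
        if len(self.contaminations) >= 0.5 * self.n_lots:
            raise ValueError("contamination fraction must stay below 0.5")
        for c in self.contaminations:
            if not 0 <= c.lot_index < self.n_lots:
                raise ValueError(f"contaminated lot index {c.lot_index} out of range")


def default_contaminations(n_lots: int = 58) -> list[Contamination]:
    """Three planted abnormal lots: inflated LP2 noise, an LP1 plateau shift,
    and a QDB shift (at fixed fractional positions of the campaign)."""
    return [
        Contamination(lot_index=int(0.37 * n_lots), mechanism="noise_inflation", signal="LP2", factor=1.3),
        Contamination(lot_index=int(0.70 * n_lots), mechanism="plateau_shift", signal="LP1", delta=3.0, plateau_index=2),
        Contamination(lot_index=int(0.92 * n_lots), mechanism="qdb_shift", delta=4.0, n_features=3),
    ]


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    #: lot -> signal -> list of (start_index, end_index, kind) step phases
    step_phases: dict[str, dict[str, list[tuple[int, int, str]]]] = field(default_factory=dict)
    #: lot -> phase name -> (start_time, end_time) of the four LP phases
    rule_phases: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    #: lot -> sample indices (within the lot's SF3 segment) occupied by spikes
    spike_indices: dict[str, np.ndarray] = field(default_factory=dict)
    #: lot -> clean (spike- and noise-bearing-free) SF3 values on the full grid
    clean_sf3: dict[str, np.ndarray] = field(default_factory=dict)
    #: index of the first sample of the terminal SF2 peak, per lot
    sf2_peak_onset: dict[str, int] = field(default_factory=dict)
    #: lot -> contamination mechanism (absent = normal lot)
    contaminated: dict[str, str] = field(default_factory=dict)
    #: QDB column -> true mean
    qdb_means: dict[str, float] = field(default_factory=dict)
    #: lot -> stream sample indices per SF signal (sample <-> lot map)
    stream_assignment: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)


def default_step_config() -> StepConfig:
    """Detector settings matched to the default profiles' duration ranges."""
    return StepConfig(
        lookahead=1,
        threshold0=None,
        duration_bounds={"slope": (180.0, 7200.0), "plateau": (600.0, 1e9)},
        threshold_step=1.5,
        max_iterations=20,
    )


def _grid(total: float, dt: float) -> np.ndarray:
    return np.arange(0.0, total + 0.5 * dt, dt)


def _template_phase_indices(profile: StepProfile, times: np.ndarray) -> list[tuple[int, int, str]]:
    """Ground-truth (start, end, kind) index intervals on the sample grid.

    The detector attributes a sample to a slope as soon as its value leaves
    the plateau level, so a slope starts at the first sample strictly after
    the plateau's end and closes one past the first sample at or beyond the
    ramp's end.
    """
    out = []
    prev = 0
    breaks = profile.breakpoints()
    n = times.size
    for seg_idx, (t0, t1, kind) in enumerate(breaks):
        if kind == "plateau":
            continue
        s = int(np.searchsorted(times, t0, side="right"))
        e = min(int(np.searchsorted(times, t1, side="left")) + 1, n)
        if s > prev:
            out.append((prev, s, "plateau"))
        out.append((s, e, "slope"))
        prev = e
    if prev < n:
        out.append((prev, n, "plateau"))
    return out


def _jitter_profile(profile: StepProfile, rng: np.random.Generator, spec: CampaignSpec) -> StepProfile:
    scale = np.ptp([lvl for lvl, _ in profile.plateaus]) or abs(profile.plateaus[0][0]) or 1.0
    plateaus = tuple(
        (
            lvl + rng.normal(0.0, spec.level_jitter * scale),
            dur * (1.0 + rng.uniform(-spec.duration_jitter, spec.duration_jitter)) if dur > 0 else dur,
        )
        for lvl, dur in profile.plateaus
    )
    ramps = tuple(
        d * (1.0 + rng.uniform(-spec.duration_jitter, spec.duration_jitter)) for d in profile.ramps
    )
    return StepProfile(plateaus=plateaus, ramps=ramps, sigma=profile.sigma, unit=profile.unit)


def _clean_batch(lot_id: str, profiles: dict[str, StepProfile], dt: float) -> Batch:
    """Noise-free batch used to evaluate rule predicates for ground truth."""
    batch = Batch(lot_id=lot_id)
    for name, prof in profiles.items():
        times = _grid(prof.total_duration, dt)
        batch.add_series(
            TimeSeries(name, times, prof.evaluate(times), unit=prof.unit, lot_id=lot_id)
        )
    return batch


def _rule_ground_truth(clean: Batch) -> dict[str, tuple[float, float]]:
    ruleset = default_lp_ruleset()
    resolved: dict = {}
    out: dict[str, tuple[float, float]] = {}
    from .phase_rules import apply_ruleset

    result = apply_ruleset(ruleset, clean)
    if result.failures:
        raise ValueError(f"generator template violates the bundled rule set: {result.failures}")
    for phase in result.phases:
        out[phase.label] = (phase.start_time, phase.end_time)
    return out


def generate_campaign(
    spec: CampaignSpec | None = None,
) -> tuple[list[Batch], list[TimeSeries], GroundTruth]:
    """Build a campaign: batches (LP series + QDB), the continuous SF stream,
    and the retained ground truth.

    The SF stream is returned un-contextualized (no lot ids), exactly as the
    filtration historian would deliver it; the QDB records carry the
    intervals needed to cut it apart.
    """
    spec = spec or CampaignSpec()
    rng = np.random.default_rng(spec.master_seed)
    lot_ids = [f"L{idx + 1:03d}" for idx in range(spec.n_lots)]
    contam_by_lot = {lot_ids[c.lot_index]: c for c in spec.contaminations}

    gt = GroundTruth()
    # ---------------- QDB features: factor structure + noise + constants
    n_var = spec.n_qdb_features - spec.n_qdb_constant
    loadings = rng.normal(0.0, 1.0, size=(n_var, spec.n_qdb_factors))
    col_mu = rng.normal(50.0, 20.0, size=n_var)
    col_sd = rng.uniform(0.5, 5.0, size=n_var)
    qdb_cols = [f"CQA{j + 1:03d}" for j in range(spec.n_qdb_features)]
    factors = rng.normal(0.0, 1.0, size=(spec.n_lots, spec.n_qdb_factors))
    noise = rng.normal(0.0, 1.0, size=(spec.n_lots, n_var))
    raw = factors @ loadings.T + noise
    raw = raw / np.sqrt((loadings**2).sum(axis=1) + 1.0)  # unit variance per column
    qdb_values = col_mu + col_sd * raw
    const_vals = rng.uniform(1.0, 10.0, size=spec.n_qdb_constant)
    for lot_pos, lot in enumerate(lot_ids):
        c = contam_by_lot.get(lot)
        if c is not None and c.mechanism == "qdb_shift":
            shift_cols = rng.choice(n_var, size=c.n_features, replace=False)
            qdb_values[lot_pos, shift_cols] += c.delta * col_sd[shift_cols]
            gt.contaminated[lot] = "qdb_shift"
    for j, col in enumerate(qdb_cols):
        gt.qdb_means[col] = float(col_mu[j]) if j < n_var else float(const_vals[j - n_var])

    # ---------------- per-lot series
    batches: list[Batch] = []
    records: list[QDBRecord] = []
    sf_stream_parts: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
        name: [] for name in spec.sf_profiles
    }
    gt_stream_idx: dict[str, dict[str, np.ndarray]] = {name: {} for name in spec.sf_profiles}
    stream_pos = {name: 0 for name in spec.sf_profiles}
    campaign_t0 = spec.start

    for lot_pos, lot in enumerate(lot_ids):
        lot_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        c = contam_by_lot.get(lot)

        lp_profiles: dict[str, StepProfile] = {}
        for name, prof in spec.lp_profiles.items():
            jit = _jitter_profile(prof, lot_rng, spec)
            if c is not None and c.mechanism == "plateau_shift" and c.signal == name:
                plateaus = list(jit.plateaus)
                lvl, dur = plateaus[c.plateau_index]
                plateaus[c.plateau_index] = (lvl + c.delta, dur)
                jit = StepProfile(tuple(plateaus), jit.ramps, jit.sigma, jit.unit)
                gt.contaminated[lot] = "plateau_shift"
            lp_profiles[name] = jit

        clean = _clean_batch(lot, lp_profiles, LP_DT)
        gt.rule_phases[lot] = _rule_ground_truth(clean)
        gt.step_phases[lot] = {}

        batch = Batch(lot_id=lot)
        for name, prof in lp_profiles.items():
            times = _grid(prof.total_duration, LP_DT)
            sigma = prof.sigma * spec.noise_scale
            sigma *= 1.0 + lot_rng.uniform(-spec.noise_jitter, spec.noise_jitter)
            if c is not None and c.mechanism == "noise_inflation" and c.signal == name:
                sigma *= c.factor
                gt.contaminated[lot] = "noise_inflation"
            values = prof.evaluate(times) + lot_rng.normal(0.0, sigma, size=times.size)
            batch.add_series(TimeSeries(name, times, values, unit=prof.unit, lot_id=lot))
            gt.step_phases[lot][name] = _template_phase_indices(prof, times)

        # ------------ sterile filtration segment of this lot
        sf_offset = lot_pos * (SF_SPAN + SF_GAP)
        lot_start = campaign_t0 + _dt.timedelta(seconds=sf_offset)
        sf_times = _grid(SF_SPAN - SF_DT, SF_DT)  # stays inside [start, end)
        for name, prof in spec.sf_profiles.items():
            sigma = prof.sigma * spec.noise_scale
            clean_vals = prof.evaluate(sf_times)
            values = clean_vals + lot_rng.normal(0.0, sigma, size=sf_times.size)
            if name == "SF2":
                onset_t = prof.plateaus[0][1]
                gt.sf2_peak_onset[lot] = int(np.searchsorted(sf_times, onset_t, side="right"))
            if name == "SF3":
                gt.clean_sf3[lot] = values.copy()  # pre-spike (noise kept: spikes are the artifact)
                spike_idx: list[int] = []
                n_spike_samples = max(1, int(round(spec.spike_duration / SF_DT)))
                # keep spikes clear of the segment edges and of each other
                lo, hi = 5, sf_times.size - 5 - n_spike_samples
                starts = np.sort(lot_rng.choice(np.arange(lo, hi, 3 * n_spike_samples), size=spec.spikes_per_lot, replace=False))
                for s in starts:
                    width = lot_rng.integers(2, n_spike_samples + 1)
                    top = spec.spike_magnitude * (1.0 + 0.05 * lot_rng.standard_normal(width))
                    values[s : s + width] += top
                    spike_idx.extend(range(s, s + width))
                gt.spike_indices[lot] = np.asarray(spike_idx, dtype=int)
            abs_times = sf_offset + sf_times
            sf_stream_parts[name].append((abs_times, values))
            n = sf_times.size
            gt_stream_idx[name][lot] = np.arange(stream_pos[name], stream_pos[name] + n)
            stream_pos[name] += n

        feats = {col: float(qdb_values[lot_pos, j]) for j, col in enumerate(qdb_cols[:n_var])}
        feats.update({col: float(const_vals[j]) for j, col in enumerate(qdb_cols[n_var:])})
        record = QDBRecord(
            lot_id=lot,
            features=feats,
            step_intervals={
                "sterile_filtration": (lot_start, lot_start + _dt.timedelta(seconds=SF_SPAN)),
                "lyophilization": (
                    lot_start + _dt.timedelta(seconds=SF_SPAN + 1800),
                    lot_start + _dt.timedelta(seconds=SF_SPAN + 1800 + spec.lp_profiles["LP4"].total_duration),
                ),
            },
        )
        records.append(record)
        batch.qdb = record
        batches.append(batch)

    gt.stream_assignment = gt_stream_idx

    sf_units = {name: prof.unit for name, prof in spec.sf_profiles.items()}
    stream = []
    for name, parts in sf_stream_parts.items():
        times = np.concatenate([t for t, _ in parts])
        values = np.concatenate([v for _, v in parts])
        stream.append(
            TimeSeries(
                name, times, values, unit=sf_units[name], lot_id=None, start_timestamp=campaign_t0
            )
        )
    return batches, stream, gt


def default_feature_specs(spec: CampaignSpec | None = None) -> list[FeatureSpec]:
    """The feature definitions matching the default campaign templates.

    27 step phases x 4 statistics + whole-signal mean/min/max for SF2 and
    SF3 + the four LP phases x (mean, min, max, duration) = 130 extracted
    features per lot.
    """
    spec = spec or CampaignSpec()
    specs: list[FeatureSpec] = []
    for name, prof in spec.lp_profiles.items():
        if name == "LP4":
            continue  # LP4 is covered by the rule phases
        n_plateau = len(prof.plateaus)
        n_slope = len(prof.ramps)
        for idx in range(n_plateau):
            for stat in ("mean", "min", "max", "plateau_std"):
                specs.append(FeatureSpec(name, f"plateau{idx + 1:02d}", stat))
        for idx in range(n_slope):
            for stat in ("mean", "min", "max", "slope_residual_rmse"):
                specs.append(FeatureSpec(name, f"slope{idx + 1:02d}", stat))
    for stat in ("mean", "min", "max", "plateau_std"):
        specs.append(FeatureSpec("SF1", "plateau01", stat))
    for name in ("SF2", "SF3"):
        for stat in ("mean", "min", "max"):
            specs.append(FeatureSpec(name, "__all__", stat))
    for phase in ("LP-Phase 1", "LP-Phase 2", "LP-Phase 3", "LP-Phase 4"):
        for stat in ("mean", "min", "max", "duration_seconds"):
            specs.append(FeatureSpec("LP4", phase, stat))
    return specs


def generate_noise_study(
    snr_grid: list[float],
    n_seeds: int = 50,
    lookahead: int = 1,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Boundary-recovery rate of the step detector across signal-to-noise ratios.

    For each SNR (smallest plateau step divided by noise sigma; ``inf`` means
    noise-free) a compact four-plateau template is simulated ``n_seeds``
    times and segmented; the recovery rate is the fraction of true
    boundaries matched within ``lookahead + 2`` samples.
    """
    from .phase_step import detect_step_phases

    if not snr_grid:
        raise ValueError("SNR grid must be non-empty")
    profile = StepProfile(
        plateaus=((0.0, 100.0), (1.0, 80.0), (3.0, 90.0), (2.0, 120.0)),
        ramps=(2.0, 2.0, 2.0),  # sharp setpoint ramps, the shape the detector targets
    )
    min_step = 1.0
    times = _grid(profile.total_duration, 1.0)
    clean = profile.evaluate(times)
    truth = _template_phase_indices(profile, times)
    true_bounds = sorted({s for s, _, _ in truth} | {e for _, e, _ in truth})
    cfg = StepConfig(
        lookahead=lookahead,
        duration_bounds={"slope": (1.5, 20.0), "plateau": (40.0, 1e9)},
    )
    rng = np.random.default_rng(master_seed)
    rows = []
    for snr in snr_grid:
        sigma = 0.0 if np.isinf(snr) else min_step / snr
        hits = total = 0
        for _ in range(n_seeds):
            values = clean + rng.normal(0.0, sigma, size=times.size) if sigma else clean.copy()
            seg = detect_step_phases(TimeSeries("study", times, values), cfg)
            found = sorted({p.start_index for p in seg.phases} | {p.end_index for p in seg.phases})
            for b in true_bounds:
                total += 1
                if min(abs(b - f) for f in found) <= lookahead + 2:
                    hits += 1
        rows.append({"snr": snr, "recovery_rate": hits / total, "n_boundaries": total})
    return pd.DataFrame(rows)
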