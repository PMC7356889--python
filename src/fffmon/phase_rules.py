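"""Phases whose boundaries are predicates over several aligned signals.

Some process phases cannot be read off a single trace: e.g. the four
lyophilization phases of the chamber-vacuum signal LP4 are bounded by events
on LP3 (the two vacuum gauges converging), on LP1 (the shelf-heating ramp)
and on LP4 itself (the vacuum returning to an earlier level).  Each phase is
declared as a :class:`PhaseRule` with a start and an end predicate plus a
``run_order``; rules are evaluated in ascending run order so a rule may
reference the boundaries of phases resolved before it.

The bundled lyophilization rule set (``default_lp_ruleset``) encodes:

=============  =========  =====================================================
phase          run order  boundaries
=============  =========  =====================================================
LP-Phase 1     2          start of LP4  ..  start of LP-Phase 2
LP-Phase 2     1          first time |LP3-LP4| relative difference < 20%
                          ..  onset of the increasing LP1 slope
LP-Phase 3     3          end of LP-Phase 2  ..  LP4 back at its LP-Phase-2
                          start value (within tolerance)
LP-Phase 4     4          end of LP-Phase 3  ..  end of LP4
=============  =========  =====================================================

Together the four phases tile LP4's support without gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .batch import Batch, TimeSeries
from .cleaning import estimate_noise_sigma
from .phase_step import Phase

__all__ = [
    "Predicate",
    "PhaseRule",
    "RuleSet",
    "RuleResult",
    "PredicateError",
    "evaluate_predicate",
    "apply_ruleset",
    "default_lp_ruleset",
    "load_ruleset",
]


class PredicateError(ValueError):
    """A predicate could not be satisfied on the given batch."""


@dataclass
class Predicate:
    """A tagged boundary condition.

    Supported kinds and their parameters:

    * ``signal_start(signal)`` / ``signal_end(signal)``
    * ``rel_diff_below(signal_a, signal_b, fraction)`` — first time where
      ``|a-b| / max(|a|,|b|)`` drops below ``fraction`` on the union grid
      (the coarser signal linearly interpolated)
    * ``slope_onset(signal, direction, threshold?, lookahead, min_run)`` —
      first sustained signed lookahead difference beyond the threshold
      (default 6 x the signal's noise sigma)
    * ``value_return(signal, reference, search_from, tolerance_fraction,
      window_seconds?)`` — first time after ``search_from`` (a phase
      boundary) at which the signal is back within
      ``tolerance_fraction x value-span`` of its value at ``reference``
      (another phase boundary); ``window_seconds`` optionally caps the search
    * ``phase_boundary(phase, which)`` — reuse a resolved phase's boundary
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = {
            "signal_start", "signal_end", "rel_diff_below",
            "slope_onset", "value_return", "phase_boundary",
        }
        if self.kind not in known:
            raise ValueError(f"unknown predicate kind {self.kind!r}")
        frac = self.params.get("fraction")
        if frac is not None and not (0 < frac < 1):
            raise ValueError("fraction must lie in (0, 1)")
        tol = self.params.get("tolerance_fraction")
        if tol is not None and not (0 < tol < 1):
            raise ValueError("tolerance_fraction must lie in (0, 1)")
        win = self.params.get("window_seconds")
        if win is not None and win <= 0:
            raise ValueError("window_seconds must be positive")

    def referenced_phases(self) -> list[str]:
        out = []
        if self.kind == "phase_boundary":
            out.append(self.params["phase"])
        if self.kind == "value_return":
            out.append(self.params["reference"][0])
            out.append(self.params["search_from"][0])
        return out


@dataclass
class PhaseRule:
    phase_name: str
    run_order: int
    start_predicate: Predicate
    end_predicate: Predicate
    target_signal: str

    def __post_init__(self) -> None:
        if self.run_order < 1:
            raise ValueError("run_order must be a positive integer")


@dataclass
class RuleSet:
    rules: list[PhaseRule]

    def __post_init__(self) -> None:
        orders = [r.run_order for r in self.rules]
        if len(set(orders)) != len(orders):
            raise ValueError("run_order values must be unique within a rule set")
        resolved_by = {r.phase_name: r.run_order for r in self.rules}
        for rule in self.rules:
            for pred in (rule.start_predicate, rule.end_predicate):
                for ref in pred.referenced_phases():
                    if ref not in resolved_by:
                        raise ValueError(f"rule {rule.phase_name!r} references unknown phase {ref!r}")
                    if resolved_by[ref] >= rule.run_order:
                        raise ValueError(
                            f"rule {rule.phase_name!r} references phase {ref!r} "
                            "that is not resolved earlier in the run order"
                        )

    def in_run_order(self) -> list[PhaseRule]:
        return sorted(self.rules, key=lambda r: r.run_order)


@dataclass
class RuleResult:
    phases: list[Phase]
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _union_grid_pair(a: TimeSeries, b: TimeSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo = max(a.times[0], b.times[0])
    hi = min(a.times[-1], b.times[-1])
    if lo >= hi:
        raise PredicateError(f"signals {a.signal_name!r} and {b.signal_name!r} do not overlap in time")
    grid = np.union1d(a.times, b.times)
    grid = grid[(grid >= lo) & (grid <= hi)]
    return grid, np.interp(grid, a.times, a.values), np.interp(grid, b.times, b.values)


def _boundary_time(resolved: dict[str, Phase], name: str, which: str) -> float:
    if name not in resolved:
        raise PredicateError(f"phase {name!r} not yet resolved")
    phase = resolved[name]
    if which == "start":
        return phase.start_time
    if which == "end":
        return phase.end_time
    raise ValueError(f"which must be 'start' or 'end', got {which!r}")


def evaluate_predicate(
    pred: Predicate, batch: Batch, resolved_phases: dict[str, Phase] | None = None
) -> float:
    """Earliest time (seconds) at which the predicate holds on the batch."""
    resolved = resolved_phases or {}
    p = pred.params

    def series(name: str) -> TimeSeries:
        try:
            return batch.series[name]
        except KeyError:
            raise PredicateError(f"batch {batch.lot_id!r} lacks signal {name!r}") from None

    if pred.kind == "signal_start":
        return float(series(p["signal"]).times[0])
    if pred.kind == "signal_end":
        return float(series(p["signal"]).times[-1])

    if pred.kind == "phase_boundary":
        return _boundary_time(resolved, p["phase"], p["which"])

    if pred.kind == "rel_diff_below":
        a, b = series(p["signal_a"]), series(p["signal_b"])
        grid, va, vb = _union_grid_pair(a, b)
        denom = np.maximum(np.abs(va), np.abs(vb))
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(denom > 0, np.abs(va - vb) / denom, 0.0)
        hits = np.flatnonzero(rel < p["fraction"])
        if hits.size == 0:
            raise PredicateError(
                f"rel_diff_below({p['signal_a']}, {p['signal_b']}, {p['fraction']}) never satisfied"
            )
        return float(grid[hits[0]])

    if pred.kind == "slope_onset":
        ts = series(p["signal"])
        direction = float(p.get("direction", 1))
        i = int(p.get("lookahead", 3))
        min_run = int(p.get("min_run", 3))
        threshold = p.get("threshold")
        if threshold is None:
            threshold = 6.0 * estimate_noise_sigma(ts)
            if threshold == 0:
                threshold = np.finfo(float).tiny
        d = direction * (ts.values[i:] - ts.values[:-i]) > threshold
        if d.size >= min_run:
            run = np.convolve(d.astype(int), np.ones(min_run, dtype=int), mode="valid")
            hits = np.flatnonzero(run == min_run)
            if hits.size:
                onset = min(int(hits[0]) + 1, len(ts) - 1)
                return float(ts.times[onset])
        raise PredicateError(f"slope_onset({p['signal']}) never satisfied")

    if pred.kind == "value_return":
        ts = series(p["signal"])
        ref_name, ref_which = p["reference"]
        from_name, from_which = p["search_from"]
        t_ref = _boundary_time(resolved, ref_name, ref_which)
        t_from = _boundary_time(resolved, from_name, from_which)
        ref_value = float(np.interp(t_ref, ts.times, ts.values))
        span = float(np.ptp(ts.values))
        tol = p.get("tolerance_fraction", 0.05) * (span if span > 0 else 1.0)
        window = p.get("window_seconds")
        mask = ts.times > t_from
        if window is not None:
            mask &= ts.times <= t_from + window
        cand = np.flatnonzero(mask & (np.abs(ts.values - ref_value) <= tol))
        if cand.size == 0:
            raise PredicateError(
                f"value_return({p['signal']}) never satisfied after t={t_from:.1f}"
            )
        return float(ts.times[cand[0]])

    raise AssertionError(f"unhandled predicate {pred.kind!r}")


def _time_to_index(ts: TimeSeries, t: float, *, side: str) -> int:
    idx = int(np.searchsorted(ts.times, t, side="left"))
    if side == "end":
        if t >= ts.times[-1]:
            return len(ts)
        return idx
    return min(idx, len(ts) - 1)


def apply_ruleset(ruleset: RuleSet, batch: Batch) -> RuleResult:
    """Evaluate every rule in run order and return the phases chronologically.

    A failing predicate flags the batch: already-resolved phases are still
    returned together with a per-rule failure report, so one broken lot never
    aborts a campaign.
    """
    resolved: dict[str, Phase] = {}
    failures: dict[str, str] = {}
    for rule in ruleset.in_run_order():
        try:
            t0 = evaluate_predicate(rule.start_predicate, batch, resolved)
            t1 = evaluate_predicate(rule.end_predicate, batch, resolved)
            if not t0 < t1:
                raise PredicateError(
                    f"rule {rule.phase_name!r}: start time {t0:.1f} not before end {t1:.1f}"
                )
            ts = batch.series.get(rule.target_signal)
            if ts is None:
                raise PredicateError(f"batch lacks target signal {rule.target_signal!r}")
            i0 = _time_to_index(ts, t0, side="start")
            i1 = _time_to_index(ts, t1, side="end")
            if i1 <= i0:
                i1 = min(i0 + 1, len(ts))
                i0 = i1 - 1
            resolved[rule.phase_name] = Phase(
                label=rule.phase_name,
                kind="rule",
                start_index=i0,
                end_index=i1,
                start_time=float(t0),
                end_time=float(t1),
                signal_name=rule.target_signal,
            )
        except PredicateError as exc:
            failures[rule.phase_name] = str(exc)
    phases = sorted(resolved.values(), key=lambda ph: ph.start_time)
    return RuleResult(phases=phases, failures=failures)


def default_lp_ruleset() -> RuleSet:
    """The bundled four-phase lyophilization rule set (see module docstring)."""
    return load_ruleset(resources.files("fffmon").joinpath("data/lp_phase_rules.yaml"))


def load_ruleset(source) -> RuleSet:
    """Read a rule set from a YAML/JSON mapping, path, or dict."""
    if isinstance(source, (str, Path)):
        payload = yaml.safe_load(Path(source).read_text())
    elif hasattr(source, "read_text"):
        payload = yaml.safe_load(source.read_text())
    elif isinstance(source, dict):
        payload = source
    else:
        raise TypeError(f"cannot load rule set from {type(source).__name__}")
    rules = []
    for item in payload["rules"]:
        def _pred(spec: dict) -> Predicate:
            spec = dict(spec)
            kind = spec.pop("kind")
            for key in ("reference", "search_from"):
                if key in spec:
                    spec[key] = tuple(spec[key])
            return Predicate(kind=kind, params=spec)

        rules.append(
            PhaseRule(
                phase_name=item["phase_name"],
                run_order=int(item["run_order"]),
                start_predicate=_pred(item["start"]),
                end_predicate=_pred(item["end"]),
                target_signal=item["target_signal"],
            )
        )
    return RuleSet(rules=rules)
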