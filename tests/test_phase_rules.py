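import numpy as np
import pytest

from fffmon.batch import Batch
from fffmon.phase_step import Phase
from fffmon.phase_rules import (
    PhaseRule,
    Predicate,
    PredicateError,
    RuleSet,
    apply_ruleset,
    default_lp_ruleset,
    evaluate_predicate,
)
from fffmon.synthetic import CampaignSpec, generate_campaign

from conftest import make_ts


def _batch(**series):
    b = Batch(lot_id="L")
    for name, ts in series.items():
        ts.signal_name = name
        b.add_series(ts)
    return b


class TestPredicates:
    def test_signal_start_and_end(self):
        b = _batch(LP4=make_ts(np.zeros(10), dt=2.0))
        assert evaluate_predicate(Predicate("signal_start", {"signal": "LP4"}), b) == 0.0
        assert evaluate_predicate(Predicate("signal_end", {"signal": "LP4"}), b) == 18.0

    def test_rel_diff_below_closed_form(self):
        # a constant at 100, b ramping 0 -> 100 over 100 s; the symmetric
        # normalization divides by max(|a|,|b|) = 100 while b < 100, so
        # |100 - b|/100 < 0.2 first holds strictly after t = 80 s
        times = np.arange(101) * 1.0
        b = _batch(
            a=make_ts(np.full(101, 100.0)),
            b=make_ts(times.copy()),
        )
        t = evaluate_predicate(
            Predicate("rel_diff_below", {"signal_a": "a", "signal_b": "b", "fraction": 0.2}), b
        )
        assert t == 81.0  # first grid point with b > 80

    def test_rel_diff_never_satisfied_raises(self):
        b = _batch(a=make_ts(np.full(10, 100.0)), b=make_ts(np.zeros(10)))
        with pytest.raises(PredicateError, match="never satisfied"):
            evaluate_predicate(
                Predicate("rel_diff_below", {"signal_a": "a", "signal_b": "b", "fraction": 0.2}), b
            )

    def test_slope_onset_finds_first_increasing_ramp(self):
        values = np.concatenate([np.full(50, -40.0), np.linspace(-40, -5, 20), np.full(50, -5.0)])
        b = _batch(LP1=make_ts(values, dt=60.0))
        t = evaluate_predicate(
            Predicate("slope_onset", {"signal": "LP1", "direction": 1, "threshold": 1.0}), b
        )
        assert 49 * 60.0 <= t <= 52 * 60.0

    def test_slope_onset_direction_skips_decreasing_ramp(self):
        values = np.concatenate([np.full(30, 0.0), np.linspace(0, -30, 10),
                                 np.full(30, -30.0), np.linspace(-30, 5, 10), np.full(30, 5.0)])
        b = _batch(LP1=make_ts(values, dt=1.0))
        t = evaluate_predicate(
            Predicate("slope_onset", {"signal": "LP1", "direction": 1, "threshold": 1.0}), b
        )
        assert t >= 65.0  # near the rise (index 70), far past the fall (index 30)

    def test_value_return_triangle_symmetry(self):
        # symmetric rise and fall: the reference value at the rise onset is
        # met again at the mirrored sample on the falling flank
        up = np.linspace(0, 10, 51)
        values = np.concatenate([np.zeros(20), up, up[::-1][1:], np.zeros(20)])
        b = _batch(y=make_ts(values, dt=1.0))
        resolved = {"anchor": Phase("anchor", "rule", 25, 30, 25.0, 30.0)}
        t = evaluate_predicate(
            Predicate(
                "value_return",
                {
                    "signal": "y",
                    "reference": ("anchor", "start"),
                    "search_from": ("anchor", "end"),
                    "tolerance_fraction": 0.02,
                },
            ),
            b,
            resolved,
        )
        # rise onset at sample 20 + 5 -> value 1.0; mirrored on the fall:
        # peak at 70, value 1.0 again at 115
        assert abs(t - 115.0) <= 1.0

    def test_phase_boundary_requires_resolution(self):
        b = _batch(y=make_ts(np.zeros(10)))
        with pytest.raises(PredicateError, match="not yet resolved"):
            evaluate_predicate(Predicate("phase_boundary", {"phase": "missing", "which": "start"}), b)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            Predicate("rel_diff_below", {"signal_a": "a", "signal_b": "b", "fraction": 1.5})


class TestRuleSet:
    def test_duplicate_run_order_rejected(self):
        rule = lambda name, order: PhaseRule(
            name, order,
            Predicate("signal_start", {"signal": "y"}),
            Predicate("signal_end", {"signal": "y"}),
            "y",
        )
        with pytest.raises(ValueError, match="unique"):
            RuleSet([rule("a", 1), rule("b", 1)])

    def test_forward_reference_rejected(self):
        early = PhaseRule(
            "early", 1,
            Predicate("signal_start", {"signal": "y"}),
            Predicate("phase_boundary", {"phase": "late", "which": "start"}),
            "y",
        )
        late = PhaseRule(
            "late", 2,
            Predicate("signal_start", {"signal": "y"}),
            Predicate("signal_end", {"signal": "y"}),
            "y",
        )
        with pytest.raises(ValueError, match="run order"):
            RuleSet([early, late])

    def test_single_rule_spans_whole_signal(self):
        ruleset = RuleSet([
            PhaseRule(
                "whole", 1,
                Predicate("signal_start", {"signal": "y"}),
                Predicate("signal_end", {"signal": "y"}),
                "y",
            )
        ])
        b = _batch(y=make_ts(np.arange(20) * 1.0))
        result = apply_ruleset(ruleset, b)
        assert result.ok
        (phase,) = result.phases
        assert (phase.start_index, phase.end_index) == (0, 20)

    def test_declaration_order_irrelevant(self, small_campaign):
        batches, _, _ = small_campaign
        ruleset = default_lp_ruleset()
        shuffled = RuleSet(rules=list(reversed(ruleset.rules)))
        a = apply_ruleset(ruleset, batches[0])
        b = apply_ruleset(shuffled, batches[0])
        assert [(p.label, p.start_time, p.end_time) for p in a.phases] == [
            (p.label, p.start_time, p.end_time) for p in b.phases
        ]

    def test_predicate_failure_flags_batch_with_partial_result(self):
        b = _batch(
            LP4=make_ts(np.linspace(1, 0.1, 50), dt=60.0),
            LP3=make_ts(np.full(50, 0.2), dt=60.0),
            # LP1 missing: the LP-Phase 2 end predicate cannot be evaluated
        )
        result = apply_ruleset(default_lp_ruleset(), b)
        assert not result.ok
        assert "LP-Phase 2" in result.failures


class TestBundledRules:
    def test_encodes_20pct_rel_diff_trigger(self):
        ruleset = default_lp_ruleset()
        phase2 = next(r for r in ruleset.rules if r.phase_name == "LP-Phase 2")
        assert phase2.start_predicate.kind == "rel_diff_below"
        assert phase2.start_predicate.params["fraction"] == pytest.approx(0.20)
        assert {r.phase_name: r.run_order for r in ruleset.rules} == {
            "LP-Phase 1": 2, "LP-Phase 2": 1, "LP-Phase 3": 3, "LP-Phase 4": 4,
        }

    def test_four_phases_partition_lp4_support(self, small_campaign):
        batches, _, _ = small_campaign
        for batch in batches:
            result = apply_ruleset(default_lp_ruleset(), batch)
            assert result.ok
            phases = result.phases
            assert [p.label for p in phases] == [
                "LP-Phase 1", "LP-Phase 2", "LP-Phase 3", "LP-Phase 4"
            ]
            lp4 = batch.series["LP4"]
            assert phases[0].start_time == lp4.times[0]
            assert phases[-1].end_time == lp4.times[-1]
            for a, b in zip(phases, phases[1:]):
                assert a.end_time == b.start_time
                assert a.start_time < a.end_time

    def test_boundaries_match_generator_ground_truth(self, small_campaign):
        batches, _, gt = small_campaign
        dt = 60.0
        for batch in batches:
            result = apply_ruleset(default_lp_ruleset(), batch)
            for phase in result.phases:
                t0, t1 = gt.rule_phases[batch.lot_id][phase.label]
                assert abs(phase.start_time - t0) <= 2 * dt
                assert abs(phase.end_time - t1) <= 2 * dt

    def test_noisy_campaign_boundaries(self, contaminated_campaign):
        batches, _, gt = contaminated_campaign
        for batch in batches:
            result = apply_ruleset(default_lp_ruleset(), batch)
            assert result.ok, result.failures
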