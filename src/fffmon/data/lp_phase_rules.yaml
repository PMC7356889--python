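# Bundled lyophilization phase rules: four contiguous phases on the
# chamber-vacuum signal LP4, driven by events on LP3, LP1 and LP4 itself.
# Rules are evaluated by ascending run_order, so LP-Phase 2 (run order 1)
# anchors the boundaries the other three phases reference.
rules:
  - phase_name: LP-Phase 1
    run_order: 2
    target_signal: LP4
    start: {kind: signal_start, signal: LP4}
    end: {kind: phase_boundary, phase: LP-Phase 2, which: start}
  - phase_name: LP-Phase 2
    run_order: 1
    target_signal: LP4
    start: {kind: rel_diff_below, signal_a: LP3, signal_b: LP4, fraction: 0.20}
    end: {kind: slope_onset, signal: LP1, direction: 1}
  - phase_name: LP-Phase 3
    run_order: 3
    target_signal: LP4
    start: {kind: phase_boundary, phase: LP-Phase 2, which: end}
    end:
      kind: value_return
      signal: LP4
      reference: [LP-Phase 2, start]
      search_from: [LP-Phase 2, end]
      tolerance_fraction: 0.05
  - phase_name: LP-Phase 4
    run_order: 4
    target_signal: LP4
    start: {kind: phase_boundary, phase: LP-Phase 3, which: end}
    end: {kind: signal_end, signal: LP4}
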