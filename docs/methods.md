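# Methods

`fffmon` turns raw formulation/fill/finish (FFF) campaign data — per-lot
quality-database (QDB) rows and multi-signal sensor time series from sterile
filtration (SF1–SF3) and lyophilization (LP1–LP7) — into a lot × feature
matrix and a robust multivariate outlier map. This note documents the model
choices, defaults, and known limitations.

## Batch alignment

Lots are the unit of analysis. Lyophilization tables carry lot labels and
join directly; the sterile-filtration historian emits one continuous,
unlabeled stream spanning months, which is cut into per-lot segments using
the filtration start/end timestamps stored in the QDB. Attribution is
half-open, `start <= t < end`, so adjacent lots can never claim the same
sample; every stream sample is assigned to at most one lot and the
assigned/unassigned counts are reported, never silently dropped. Analysis
operates on seconds-from-start per series; absolute datetimes survive only
in the QDB record and in the stream anchor. No resampling happens at
ingest — the phase algorithms accept the native (possibly irregular) grid,
with a warning when the max/median inter-sample gap exceeds 10.

## Sensor cleaning

Two artifact classes are removed before analysis, both by deletion (never
interpolation — cleaning must not fabricate data, and everything downstream
tolerates non-uniform grids):

* **Terminal pressure peak (SF2).** At the end of a filtration run the
  applied pressure spikes; the cleaner truncates the terminal suffix whose
  backward-difference slope magnitude stays above
  `terminal_slope_threshold` (default 1e-3 bar/s in the pipeline config).
  The suffix ends at the last *sustained* (3-sample) low-slope run, so one
  noisy sub-threshold sample inside the peak cannot stop the scan early.
  Interior slopes are never touched.
* **Operator spikes (SF3).** People stepping on the scale produce tall,
  short excursions on the product-weight signal. An excursion opens where
  the centered 3-sample slope magnitude exceeds `spike_slope_threshold`
  (default `10·σ_noise / median Δt` — the true drain slope is far below
  that) and every sample is deleted until the value returns within `3·σ` of
  the pre-excursion level or `spike_max_duration` (default 600 s) elapses.
  Excursion edges are refined by value, not slope, because the centered
  window elevates the slope of the clean neighbours.

The noise scale `σ` is estimated from first differences divided by √2,
robustly (1.4826 × MAD) by default, so sparse ramp samples do not inflate it.
Both cleaners are idempotent, and the cleaned series is always a subsequence
of the input. Removal of more than 50% of samples aborts with an error —
that is a threshold misconfiguration, not a cleaning outcome.

## Step-signal phase setting

FFF signals are dominated by plateaus joined by sharp setpoint ramps. A
slope opens at the first sample `t` where `|y_t − y_{t+i}| > threshold`
(lookahead `i`, default 1 sample) and closes at the first later sample where
the difference falls back to or below the threshold; the stretches between
slopes are plateaus. Comparisons are made `i` samples apart (not per unit
time); duration constraints are checked in seconds.

The threshold adapts: starting from `threshold0` (default `3·σ_noise`, which
keeps the per-comparison false-start rate near 0.3%), each candidate
segmentation is validated against per-kind duration bounds. A phase shorter
than its minimum raises the threshold by ×1.5, one longer than its maximum
lowers it by the same factor, and the scan restarts globally — up to 20
iterations, after which the iteration with the fewest violations is returned
flagged as non-converged. Default bounds in the pipeline are 180 s–7200 s
for slopes and ≥600 s for plateaus; the slope minimum is deliberately three
samples at the 60-s lyophilization grid, because two-sample noise excursions
otherwise survive as phantom slopes and shift every later phase label.
A signal that opens mid-slope yields a leading slope phase and a flag.

The detector is deterministic, scale-equivariant (scaling values and
threshold together leaves boundaries untouched), and recovers noise-free
constructions exactly (within the lookahead).

## Multi-signal (intertwined) phases

Some process phases are defined by events on *other* signals. Phases are
declared as rules — a start predicate, an end predicate, and a `run_order`;
rules are evaluated in ascending run order, so later rules may reference the
boundaries of phases already resolved. The predicate vocabulary:
`signal_start`, `signal_end`, `rel_diff_below(a, b, fraction)` (first time
`|a−b| / max(|a|,|b|)` drops below the fraction, signals compared on the
union grid with linear interpolation — the symmetric denominator avoids
division by near-zero on vacuum signals), `slope_onset` (first sustained
signed lookahead difference beyond a threshold, default `6·σ_noise` over 3
consecutive comparisons), `value_return` (first time after a given phase
boundary at which the signal is back within `tolerance_fraction` × its value
span of its value at a reference boundary; an optional `window_seconds` caps
the search horizon), and `phase_boundary`.

The bundled lyophilization rule set divides the chamber-vacuum signal LP4
into four contiguous phases: LP-Phase 2 (run order 1) starts where the LP3
/LP4 relative difference first drops below 20% and ends at the onset of the
increasing LP1 (shelf-heating) ramp; LP-Phase 1 runs from the start of LP4
to the start of Phase 2; LP-Phase 3 runs from the end of Phase 2 until LP4
returns to its Phase-2-start value (tolerance 5% of span, unbounded search
window); LP-Phase 4 covers the rest. The four phases tile LP4's support
exactly. A failing predicate flags the lot and returns the phases already
resolved — one broken lot does not abort a campaign.

## Feature extraction and scaling

From each phase: mean, min, max; plateaus additionally contribute their
sample standard deviation (a per-lot noise fingerprint) and slopes the RMSE
of an ordinary least-squares line fit of value on time (ramp-shape
fidelity); rule phases contribute their duration in seconds. Column names
are canonical `signal|phase|statistic`; provenance (extracted vs QDB) is
kept per column. A phase missing for one lot produces a missing value, not
a missing column.

Columns whose observed values are all equal are dropped (with a report);
columns missing in more than 20% of lots are dropped with a warning and the
remaining gaps are median-imputed (the robust PCA needs complete data).
Finally every column is centered and scaled — robustly by default
(median / 1.4826·MAD, falling back to mean/SD where the MAD is zero) — so
that the multivariate model weighs all features and lots equally.

## Robust PCA and the outlier map

`ROBPCA` is a three-stage projection-pursuit / MCD hybrid:

1. an SVD restricts the data to the affine subspace it spans;
2. Stahel–Donoho outlyingness — the largest robustly standardized projection
   over a set of directions through pairs of observations (all pairs when
   N ≤ 25, a seeded sample of 250 pairs otherwise; pair-based directions
   keep the procedure exactly rotation-equivariant) — selects the
   `h = max(⌊αN⌋, ⌊(N+k+1)/2⌋)` least outlying points (α defaults to 0.75);
3. the eigenvectors of the kept points' covariance fix a k-dimensional
   plane. Points with gross preliminary orthogonal distance (beyond a loose
   99.9% Wilson–Hilferty screen) are set aside — they project harmlessly
   into the plane and would be invisible to a score-space estimator — and a
   minimum-covariance-determinant estimate of the remaining scores, with the
   standard consistency factors and one 97.5% reweighting step, refines
   center and scatter. The MCD subset search is exact (lexicographic
   enumeration) when `C(n, h) ≤ 20 000` and FAST-MCD otherwise.

`k` is the smallest component count reaching the `variance_target`
(default 80%) of the kept points' variance, unless pinned. Every lot then
gets a score distance `SD_i = sqrt(Σ_j t_ij²/λ_j)` and an orthogonal
distance `OD_i = ‖x_i − μ − Pᵀt_i‖`. Cutoffs at the 97.5% level —
`sd_cut = sqrt(χ²_{k;0.975})`, and `od_cut` from the Wilson–Hilferty
approximation (OD^{2/3} treated as Gaussian with median/MAD location and
scale) — divide the SD/OD plane into four quadrants: regular, score
outlier, orthogonal outlier, both. Strict inequality flags; boundary
equality is regular. When `k` equals the data rank, OD is identically zero
and OD classification is suppressed.

Root-causing uses the additive decomposition
`c_ij = (x_ij − μ_j) · Σ_k P_kj t_ik / λ_k`, whose row sums reproduce
`SD_i²` exactly (an enforced invariant) — the largest `|c_ij|` point to the
features driving an outlying score.

For comparison, `ClassicalPCADiagnostics` fits ordinary PCA with the
Hotelling T² statistic (95% limit `k(N−1)(N+1)/(N(N−k)) · F_{0.95;k,N−k}`)
and the normalized DModX residual distance (95% limit
`sqrt(F_{0.95; p−k, (N−k−1)(p−k)})`). Because classical eigenvalues are
inflated by the very outliers under investigation, T² systematically masks
planted score outliers that the robust model flags — the package's
simulation studies reproduce this direction.

## The synthetic campaign generator

Real campaigns of this kind are proprietary, so the generator is first-class
code: it emulates the *statistical shape* of an FFF campaign — step-profile
templates per signal (levels, plateau durations, ramp durations), i.i.d.
Gaussian sensor noise, lot-to-lot jitter on levels (1%), durations (3%) and
noise level (3%), the SF2 terminal peak, rectangular noisy-top SF3 spikes,
a continuous absolutely-timestamped SF stream with inter-lot gaps and
matching QDB intervals, and 122 correlated QDB features (5-factor structure,
5 constant columns). The default campaign is 58 lots with 130 extracted
features, mirroring the bookkeeping of a mid-size commercial campaign.

Template levels and durations are the package's own choices, constrained by
two design rules: every ramp's per-sample increment is at least ~15–20 σ of
that signal's noise (so the adaptive threshold has a wide stable operating
band), and every bundled rule-set predicate has a unique, well-separated
crossing (e.g. LP4's value at the LP3/LP4 convergence, ≈0.25 bar, sits far
outside the 5%-of-span return tolerance around the 0.1 bar holding plateau).
Ground truth — phase boundaries, rule-phase times (obtained by evaluating
the predicates on the noise-free templates), spike indices, clean signals,
contamination labels — is retained for every lot. Everything derives from a
single master seed through per-lot child generators; no global RNG state.

Planted abnormalities: `noise_inflation` (×1.3 on one LP signal's noise —
the classic "one lot is 30% noisier" motif), `plateau_shift` (a level offset
on one plateau), `qdb_shift` (a few QDB columns moved by several column
SDs). The default contaminated campaign plants one of each.

What the generator does *not* emulate: lyophilization heat/mass-transfer
physics, drifting or autocorrelated sensor noise, missing-data patterns of
real historians, or seasonal campaign trends. Passing tests therefore
demonstrate the algorithms' contracts on step-shaped, Gaussian-noise data —
not performance on any particular plant's records.

## Numerical choices and degenerate inputs

* Constant series have noise σ = 0; thresholds derived from σ fall back to
  tiny positive values so detection remains well-defined.
* MCD ties are broken toward the lexicographically first subset; all
  stochastic direction sampling derives from the model's `random_state`.
* DModX is defined as zero when the residual space is numerically empty.
* `estimate_noise_sigma` requires ≥3 samples; series require ≥2.
* Exhaustive MCD enumeration is capped at 20 000 subsets; beyond that,
  FAST-MCD (seeded) takes over.

## Known limitations

* With p ≈ 250 features on 58 lots and k ≈ 18, the score-distance cutoff is
  close to nominal, but the Wilson–Hilferty OD cutoff is anticonservative:
  a quarter of clean lots can exceed it. Adaptive cutoff estimation is out
  of scope; treat OD flags at this shape as a ranking, not a calibrated
  test.
* Whether a planted abnormality surfaces in SD or OD depends on whether its
  direction lies inside the model plane; a lot whose only deviation is
  inflated noise on one signal typically appears as an orthogonal outlier.
* The step detector's fixed-threshold family fails gracefully (flagged
  non-convergence) but cannot segment signals whose ramps are slower than a
  few noise σ per sample.
* The rule engine covers the bundled predicate vocabulary only; it is not a
  general temporal logic.
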