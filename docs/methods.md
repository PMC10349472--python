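# Methods

This note documents the models behind `mbrtwin`, the parameters that
matter, and the design choices made where the design was genuinely open.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Growth model and backscatter readout

Batch growth of a well is lag → single-rate exponential → hard stop:

    OD(t) = od0                                  t ≤ lag
    OD(t) = od0 · exp(µ_max (t − lag))           lag < t ≤ t_stop
    OD(t) = od0 + Y·S0                           t > t_stop

with `t_stop = lag + ln(1 + Y·S0/od0)/µ_max` (substrate exhaustion,
yield `Y` in OD per g/L, initial substrate `S0` in g/L). Defaults —
µ_max = 0.4735 h⁻¹, lag = 1.5 h, S0 = 10 g/L glucose, Y = 2, od0 = 0.1 —
are calibrated so a standard inoculation reaches stationary phase after
≈ 12.7 h and crosses the 5.5 a.u. inoculation trigger after ≈ 10 h,
the magnitudes typical for wild-type *C. glutamicum* in this format.
There is no Monod saturation term: the sharp exponential-to-stationary
transition is the feature the derivative-based batch-time detector keys
on, and a hard stop reproduces it with one parameter fewer (see
Limitations for the flip side).

The instrument readout is backscatter in arbitrary units,
`gain·OD + offset + ε`, ε ~ N(0, σ). No absolute backscatter↔OD
calibration exists for these instruments, so gain and offset are free
configuration (defaults 1 a.u./OD and 0), chosen so the operational
thresholds (2, 3.7, 5.5 a.u.) fall inside the exponential phase; the
thresholds themselves are never recoverable quantities. Default noise is
σ = 0.05 a.u. (≈ 0.25 % of the curve range), the scale consistent with
the sub-2 % replicate variability these instruments deliver.
Measurements land on a fixed cycle grid: 13 min for plates with pH/DO
optodes, 4 min without. pH/DO traces are smooth placeholders only; no
estimator consumes them.

Randomness: one root seed per experiment; every well/plate/replicate
draws from a child stream derived by hashing a stable string key into a
`SeedSequence` spawn key, so single-well results are reproducible
independently of plate size or simulation order.

## Liquid handling and carry-over

All transfers are ideal volume-weighted mixing; glycerol (% w/v),
disinfectant and methanol (% v/v), substrate (g/L), inducer (µM),
product (U/mL) and biomass (OD, treated as linearly additive at these
densities) ride along as species concentrations. Density effects and
wetting films are ignored — consistent with the bench arithmetic this
mirrors (equal-volume saline addition takes 25 % glycerol to 12.5 %).

Carry-over follows the residual chain: a well retains `V_res` after
aspiration; each wash adds `V_wash` and removes back to `V_res`,
multiplying the contaminant concentration by `V_res/(V_res+V_wash)`.
Presets: 10 µL residual for solvent-like liquids (achievable with
optimised two-speed aspiration, 250 then 70 µL/s — carried as metadata,
not simulated physics), 100 µL worst case for spent culture broth. The
chain model makes both printed carry-over figures (0.02 % after two
700 µL washes, 0.002 % after three) upper bounds: the constant-factor
chain gives 0.0198 % and 0.00028 % respectively. The second printed
figure evidently stems from assumptions beyond a constant-factor chain;
the implementation reports the model value and treats both numbers as
bounds only.

A documented inconsistency in the source workflows — tube cell banks
described both as OD 30 and as "frozen at OD 20" in different contexts —
is left as-is: both dilutions are implemented per their own context.

## Orchestration

Time advances on the measurement cycle; triggers are evaluated only at
sample instants. A crossing is the first sample at or above threshold
after a sample strictly below (no interpolation), so trigger times carry
at most one cycle of error — which is also why replicate summaries floor
the SD at one cycle. Wells trigger independently; one-shot rules consume
themselves per well, which makes noise-dip re-crossings harmless.

Actions update well state through the mass-balance layer and append
immutable event records. The IPTG induction volume is not stated
anywhere as a volume, only as final concentrations (250/500 µM), so the
engine adds a configurable 20 µL bolus of a stock sized to hit the final
concentration exactly. Main cultures inherit exponential-phase inoculum
and are modelled without lag.

CIP uses barrier semantics (plate-level, after all linked wells are
sampled). Protocol durations are built from whole-plate liquid-handling
passes (default 8 min per pass) plus fixed steps: the medium-wash
protocol (disinfectant pre-wash, 800 µL disinfectant with 20 min kill
incubation, two-step removal, two 700 µL medium washes, 800 µL refill)
takes 12 passes + 20 min ≈ 1.9 h; the methanol protocol (disinfection,
400 µL methanol replacement, 10 h evaporation) ≈ 11.3 h. The 20-min
disinfectant incubation sets `viable = False`; evaporation leaves the
well dry, so the methanol route's carried-over disinfectant amount is
zero. Sterility is verified by simulating a 24 h incubation of the
refilled well and flagging any backscatter rise above a detection
threshold (default 0.2 a.u.); a zero-duration check is reported
indeterminate, never sterile.

A campaign alternates triggered cultivation runs and CIP phases with no
manual events; a run that does not complete within `max_run_h` (e.g. a
preculture that never reaches its trigger — behaviour the source
workflows leave unspecified) logs a timeout failure and aborts with the
log retained. A campaign-wide volume ledger balances dispensed volumes
against wells, waste, samples and evaporation; the discrepancy is
asserted to be zero in the tests.

## Batch-time detection

The batch time is the argmax of the first derivative of a cubic
smoothing spline fitted to the backscatter curve. The smoothing penalty
λ (scipy's `make_smoothing_spline`: minimise Σ(y−f)² + λ∫f″²) is chosen
by k-fold cross-validation (default k = 5) with interleaved folds (every
k-th sample), which keeps each fold spread over the whole time range;
the minimiser is refitted on all data. For this penalised formulation λ
is exactly invariant to rescaling the measurements (both terms scale
with y²), so the default candidate grid is a fixed log grid,
λ ∈ 10^[−6, 3], spanning effective bandwidths from about one cycle to
several hours on an hourly time axis — no variance scaling is needed or
used. The derivative is evaluated on a 0.01 h grid; the first and last
two sampling intervals are excluded (spline edge artefacts) and the
earliest time attaining the maximum wins, making results deterministic.
Replicate summaries report mean and `max(sample SD, error floor)` with
the floor defaulting to 4 min, the shortest measurement cycle.

Accuracy, measured on the package's own generators: detected batch
times are highly *reproducible* (relative SD across 12 replicates well
below 2 % at the default noise; see `examples/batch_time_detection.py`)
but carry a systematic early bias on hard-stop curves. A one-sided
derivative cliff sampled every Δ minutes cannot be localised by any
smoothed-derivative argmax to better than ~1.2 Δ (the argmax lands
inside the steepest sampling segment, while the true stop lies up to one
cycle past that segment's end), and cross-validated smoothing —
optimal for function prediction, not for corner localisation —
typically smooths harder, giving 0.2–0.7 h absolute bias at 1–3 %-of-
range noise. Smooth inflection-type transitions (logistic curves) show
no such bias, only noise-driven jitter. Consequences: replicate
*comparisons* (the platform's actual use) are unaffected because the
bias is common to all replicates; absolute one-cycle recovery of hard
stop times is not attainable with this estimator and is not claimed.

## Assay analysis

Activity follows EA = ΔA₄₁₀ · (1/m_standard) · DF with unit audit
(a.u./min)·(mM/a.u.) = mM/min = µmol/(mL·min) = U/mL. The standard curve
is OLS *with* intercept, so constant blanks cannot bias the slope — this
also answers the open question of whether blank subtraction preceded the
original slope fits: with an intercept the result is insensitive to it.
The kinetic slope is the OLS slope over the initial linear window,
defined as the first 10 reads or the longest prefix (≥ 3 reads) with
R² ≥ 0.995, whichever is shorter; the threshold is set high enough that
a single saturation-plateau read is excluded (at 0.98 one plateau read
slips through and shifts the slope by ~5 %), while realistically noisy
linear prefixes (R² ≈ 0.9998 at the simulated read noise) always pass.
Substrate concentration, read interval and window rule are not dictated
by the assay description, so all are configurable. Negative slopes are
reported as activity 0 with a `clamped` flag. Groups of exactly two
(technical duplicates) report half the absolute difference as their
error measure; larger groups report the sample SD — matching how
six-replicate and per-batch-duplicate results are displayed.

## Secretion generator and batch-effect analysis

Secreted activity is `strain mean ⊕ inducer effect + batch + bio + tech`
with independent Gaussian effects (batch shared within a run). Defaults:
batch SD 0.3 U/mL — the scale of the observed run-to-run shifts, which
reach ~0.6 U/mL for single strains — bio 0.1, tech 0.05 U/mL; the
inducer effect is additive per level by default, multiplicative by flag.
Twelve default signal-peptide means span 0.4–2.9 U/mL, strong secretors
(Bsn, NprB, NprE, YncM) to weak (Epr, Pel, YpjP). Absolute activity
levels are experimental facts, not recomputable; only the variance
structure is emulated, and recovery tests target the variance
components, never the means.

Variance decomposition is balanced one-way method-of-moments:
`MS_between = σ²_w + n·σ²_b`, `MS_within = σ²_w`; negative between-batch
estimates are truncated at zero and flagged. A full mixed model is
deliberately avoided — the quantities of interest are descriptive SDs
and one variance split. Outlier ("Golden Batch") flagging marks batches
whose mean deviates from the grand mean by more than 2 pooled
within-batch SDs of a batch mean; the threshold is configurable and the
rule is a heuristic screen, not a test. The strategy comparison reports
per-cell pooled SDs under same-plate vs spread placement and their
ratio; under a positive batch effect the spread design's SD is larger in
expectation by √((σ²_b+σ²_w)/σ²_w). Weekly stability reports accept
either raw replicate lists or mean ± SD summaries, floor SDs at the
cycle time, and report per-week between-condition differences, relative
differences against a chosen reference condition, and SD/mean relative
deviations.

## What the synthetic data does and does not show

The generators emulate: trigger-relevant curve shape, fixed-cycle
sampling, additive backscatter noise, run-level random effects with the
stated replicate structure (3 biological × 2 technical), and assay
kinetics consistent with the activity equation. They do not emulate:
mechanistic pH/DO/oxygen transfer, evaporation during cultivation,
diauxic or inhibited growth, plasmid loss, positional plate effects, or
non-Gaussian instrument artefacts. Passing recovery tests therefore
demonstrates the correctness of the arithmetic, control logic and
estimators under the stated statistical model — not robustness to real
instrument pathologies.

## Problem sizes used in tests

The suite runs desk-scale problems chosen as representative rather than
exhaustive: 48-well plates, campaigns of 1–3 runs, 100 curves for the
batch-time recovery sweep (growth rates 0.2–0.5 h⁻¹ × noise 0–3 % of
range), 200 simulated batches for variance-component recovery, and
120–200 Monte-Carlo repetitions for the strategy comparison.

## Known limitations

- The hard-stop growth model makes the derivative argmax estimator's
  corner bias (above) visible; real curves decelerate smoothly, where
  the bias is smaller but the true transition is also less well defined.
- CIP durations are pass-count × pass-time arithmetic, not robot
  kinematics; aspiration speeds affect residual-volume presets only.
- The disinfectant kill is a step function (viable → false after one
  incubation); no dose–response.
- OD additivity and linear backscatter ignore shading/saturation at very
  high cell densities.
- The inducer bolus volume is a convention (20 µL); only the final
  concentration is constrained.
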