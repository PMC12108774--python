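# Methods

## Signal model and simulator

The simulator produces a fully sampled 2D multi-gradient-echo (MGE)
acquisition of a digital phantom under continuous, sequentially
linearly phase-encoded sampling. One phase-encode line — with all of its
echoes — is acquired per TR (an MGE readout shares one excitation), and the
line is timestamped at the excitation. Measurement `m` starts at
`m · n_pe · TR` with TTL start/end events emitted per measurement, so the
total acquisition lasts `n_measurements · n_pe · TR` with no gaps
(defaults: 300 · 128 · 14 ms ≈ 9 min, matching the protocol's ~10-minute
scan).

For echo `e` at `TE_e = TE_1 + e·ΔTE` the ideal image is
`S0 · exp(−TE_e / (T2* · f(u)))`, where `f(u)` is a multiplicative T2\*
modulation evaluated at the line's normalized cardiac-cycle position `u`
(constant 1 for a static phantom). The stored k-space row is the matching
row of the centered, orthonormal 2-D DFT of that image plus complex
Gaussian noise of SD `noise_sd` per real/imaginary component per sample.
Because the phantom is piecewise constant over vials, the k-space of any
exponentially weighted image is a T2\*-dependent linear combination of
precomputed per-vial indicator spectra; the dynamic case therefore stays
exact without one FFT per line.

Deliberately **not** modeled: flip angle/T1 saturation, B0 off-resonance,
fat–water shift, coil sensitivities, respiration, and the iron-concentration
→ T2\* conversion (no relaxivity constant is needed — phantoms are specified
directly in T2\*, with defaults {4, 6, 9, 12, 16, 20} ms chosen to span the
myocardial-mimicking 4–20 ms range). Consequently, passing tests demonstrate
the correctness of the gating/binning/averaging/fitting chain, not
robustness to off-resonance, motion or multi-channel reconstruction effects
present in real scanner data.

## Heartbeat and pulse-oximetry emulation

R-R sequences come from one of: constant, uniform (mouse range 80–160 ms is
`mean 120, half-range 40`), Gaussian, or replay of recorded intervals. The
pipeline default is Gaussian with mean 120 ms and SD 3 ms (≈2.5%): large
enough to exercise the binning against beat-to-beat variability, small
enough that the 5% moving-median filter retains the overwhelming majority
of beats — mimicking slow physiological drift rather than i.i.d. jitter.
(An i.i.d. uniform 80–160 ms train would put most intervals >5% from the
local median and is therefore *not* a sensible filter input; the uniform
model is used for temporal-resolution accounting and distribution-level
tests.) A `failure_rate` deletes triggers to emulate pulse-oximetry dropouts
that merge two beats into one apparent double-length interval.

The synthetic pulse-ox trace places one Gaussian pulse (σ = 5 ms) per
trigger plus white noise. Trigger detection smooths the trace (σ = 2 ms),
picks prominence-qualified local maxima at least `min_rr` apart (default
50 ms, below the fastest mouse R-R of ~80 ms), and refines each peak by
quadratic interpolation to sub-sample precision.

## Gating rules

* **R-R validity**: interval `i` is excluded iff it deviates *strictly* more
  than 5% from the moving median of 10 consecutive intervals centered at `i`
  (even window: one extra interval on the late side; edge windows truncated;
  at least 3 intervals required). A centered window treats slow drift
  symmetrically; exactly-5% deviations are retained.
* **Phase assignment**: a line at `t` with `t_k ≤ t < t_{k+1}` in a valid
  interval gets phase `⌊(t−t_k)/(t_{k+1}−t_k) · n_phases⌋` clamped to
  `n_phases−1`; bins are half-open, so a line exactly on a trigger opens
  phase 0 of the new beat. Lines before the first trigger, at/after the
  last trigger, or inside excluded intervals are discarded (never
  extrapolated — no R-R duration is defined for them) with a recorded
  reason, and conservation (assigned + discarded = total) holds by
  construction.
* **Systole alignment**: the phase shift that puts phase 0 at systole onset
  is a user-supplied integer (`systole_phase_offset`, default 0) applied as
  a circular relabeling; the package does not try to detect systole from
  image content.

## Reconstruction

Per (echo, pe) each repetition's line is phase-corrected against the first
measurement whose lines all fall in valid R-R intervals: the phase
difference to the reference line is unwrapped along the readout and fitted
with a magnitude-weighted straight line in the centered sample index,
giving zero-order (`φ0`) and first-order (`φ1`, i.e. readout-shift) terms
that are then removed. Bins are complex-averaged (magnitude is taken only
after reconstruction), and each phase is reconstructed by the centered
orthonormal inverse 2-D DFT, making synthesis/reconstruction exact inverses.

Empty (echo, pe) bins are zero-filled with a warning; a fill fraction below
0.95 is an error unless explicitly allowed. The ~10% tolerated line loss
reflects how much triggering quality typically costs in practice; the
default 300 measurements with 10 phases fill every bin under mouse-range
heart rates.

## Fitting

Pixelwise bounded nonlinear least squares (`T2* ∈ [0.1, 100]` ms — wide
enough to bracket both the phantom range and in vivo myocardium with
margin — and `S0 > 0`), initialized from the magnitude-weighted log-linear
solution; goodness of fit is `R² = 1 − SS_res/SS_tot` on the magnitude
scale. No-signal pixels, non-convergent fits and fits pinned at a bound are
flagged and excluded from maps and ROI summaries, as are pixels with
non-positive gof. Magnitude-domain fitting is biased upward at low SNR by
the Rician noise floor; this is documented and observable (the test suite
asserts the bias grows monotonically as SNR falls) but deliberately not
corrected. The default signal mask thresholds the first-echo magnitude at
5× the background SD estimated from the image border (floored at 0.1% of
the image maximum for noiseless data); explicit ROI masks are accepted
everywhere.

## Agreement and cohort statistics

* **NEMA single-image SNR**: ROI mean divided by background-magnitude SD /
  0.66; the 0.66 factor converts the Rayleigh-distributed magnitude
  background SD to the underlying Gaussian noise SD.
* **Method agreement**: OLS slope/intercept, Pearson R², ICC(2,1) (two-way
  random, absolute agreement, single measures — the standard choice for
  method comparison, computed via pingouin), and Bland–Altman in difference
  form (bias ± 1.96·SD of paired differences).
* **Phase/group tests**: Friedman χ² across phases (with an exact zero
  statistic fallback for ties-only degenerate tables), Holm-adjusted
  pairwise Wilcoxon signed-rank tests, Mann–Whitney U on cycle-averaged
  values (exact null for ≤10 per group without ties, tie-corrected normal
  approximation otherwise), and Spearman ρ against covariates with verbal
  strength labels (very weak < 0.2 ≤ weak < 0.4 ≤ moderate < 0.6 ≤ strong
  < 0.8 ≤ very strong) and `*`/`**`/`***` significance markers.

## Problem sizes and numerical choices

The flagship validation runs the full default protocol (128×128, 300
measurements, 10 phases, six vials, noiseless) and completes in well under
a minute; property and Monte-Carlo tests use scaled-down grids (32×32 or
64×64) and 30–300 measurements, sizes at which every asserted effect
(√N SNR scaling, convergence with repetitions, ±20% modulation recovery
with r > 0.95) is comfortably resolved. Determinism: a single global seed
fans out via `numpy.random.SeedSequence` into independent per-stage child
seeds, so identical configs produce byte-identical CSV outputs.

The near-uniformity of per-phase line occupancy under constant R-R depends
on the continued-fraction structure of TR/R-R: for well-conditioned ratios
(e.g. R-R = 80·√2 ms) occupancy is within ±1 line of uniform over 300
measurements, while resonant ratios can concentrate lines in a few phases —
the reason variable (or well-chosen constant) heart rates matter for bin
filling.

## Known limitations

* Single-channel, fully sampled Cartesian data only; no undersampling or
  parallel imaging.
* The phase-correction estimator (reference measurement choice, weighting)
  is one defensible construction; scanner pipelines may differ in detail.
* No ECG or respiratory processing; gating is pulse-oximetry/trigger-based
  and free-breathing by design.
* In vivo effects (flow, motion within a phase bin, off-resonance near the
  lung–heart interface) are outside the simulator's scope; phantom-perfect
  agreement is a necessary, not sufficient, condition for in vivo accuracy.
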