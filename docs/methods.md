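# Methods

This note documents the models implemented in `plimox`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices that matter for reproducing results.

## Acquisition model

A pointwise PLIM acquisition interleaves a 10 µs excitation gate with a
290 µs TCSPC collection gate (300 µs cycle). One *repetition* accumulates a
time-binned photon histogram over 2000 cycles (0.6 s); 20 repetitions are
acquired per intravascular location. The same 2000 cycles, summed per
cycle, form the RBC-flux intensity trace I(t) with dt = 300 µs. The TCSPC
bin width is not a property of the method itself; the default is 1 µs
(290 bins), fine enough that binning bias on a 15–40 µs lifetime is
negligible, and configurable via `AcquisitionProtocol`.

## Lifetime fitting

Per location: (1) iterated two-sided Grubbs test on the 20 total photon
counts at α = 0.05 removes motion-corrupted repetitions (rejection happens
strictly before averaging); (2) surviving histograms are averaged bin-wise;
(3) the first 5 µs are discarded and the remaining 285 µs fitted with
y(t) = A·exp(−t/τ) + C by trust-region nonlinear least squares (τ, A ≥ 0).

Initialization is derivative-free and robust: C₀ = mean of the last 10% of
bins; τ₀ from the log-slope of the background-subtracted first half of the
window (guarded against non-positive values); A₀ from the first window bin.
Fitting is unweighted by default; Poisson weighting (σᵢ = √max(yᵢ, 1)) is
available via `weighted=True`. Non-convergence returns a flagged result
(`converged=False`) rather than a silent number; a decay with zero dynamic
range raises a degenerate-input error. Optimizer tolerances are 1e-14, so
noiseless model-class data are recovered to ~1e-9 relative, and the fit is
invariant to uniform scaling of the counts.

The Grubbs critical value is computed from the Student-t distribution,
G(n, α) = (n−1)/√n · √(t²/(n−2+t²)) with t = t_{α/(2n), n−2}; the
first-iteration rejection rate on null data is ≈ α (slightly conservative
by construction). Fewer than 3 repetitions pass through with a warning.

## Calibration

Lifetime → pO2 uses the linear Stern–Volmer form 1/τ = 1/τ₀ + k_q·pO2.
Probe calibration constants are temperature- and batch-specific and are
**required configuration**: the defaults τ₀ = 40 µs and
k_q = 2.78×10⁻⁴ (µs·mmHg)⁻¹ span τ ≈ 40 → 15 µs over 0–150 mmHg, the
regime of the intravascular probe at a heated objective (~36.6 °C). All
accuracy guarantees in the test suite are round-trip/self-consistent and
hold for any valid constants. A fitted τ exceeding τ₀ beyond tolerance is
a calibration violation (error, or clamped to 0 mmHg when configured —
the pipeline clamps, since photon noise at very low oxygen legitimately
produces τ̂ marginally above τ₀). If a probe's true calibration is
appreciably nonlinear in pO2, the linear form is a known divergence; the
conversion is isolated in `lifetime_to_po2`/`po2_to_lifetime` so a
different calibration can be dropped in.

pO2 → SO2 uses the Hill equation with murine coefficients h = 2.59,
P50 = 40.2 mmHg. SO2 is computed per measurement and then averaged; the
Hill transform of a mean is never used.

## Classification, layers, summaries

* Arteriole/venule calls use the day-0 (baseline) pO2 at 50 µm subpial
  depth: strictly > 66 mmHg → arteriole, ties and below → venule. The call
  is frozen and propagated to later days.
* Layers are half-open, low-inclusive: I = [0, 100), II/III = [100, 320),
  IV = [320, 450] µm, so the standard measurement depths
  {50, 100, 200, 300, 400} µm map to {I, II/III, II/III, II/III, IV} and
  every depth belongs to exactly one layer.
* CV uses the sample standard deviation (n−1). SE = sd/√n.
* The animal is the unit of averaging: per-animal layer means/CVs/DOEs are
  computed first and then averaged unweighted across animals; cohort SEs
  are between-animal SEs. Cohort CVs are means of per-animal CVs (not CVs
  of pooled vessels).
* DOE = mean(SaO2) − mean(SvO2) per layer; no SaO2 normalization (that
  variant, OEF, is deliberately not computed).
* Longitudinal ΔSO2 aligns measurement points by vessel id across days
  (Δ = value(day d) − value(day 0) within vessel), then aggregates
  per animal and per cohort.
* Primary branches of penetrating vessels (pre-capillary arterioles /
  post-capillary venules) carry a metadata flag and are excluded from all
  capillary pools.

## RBC-flux counting

Baseline: the whole-trace median by default. A short rolling median
(configurable `baseline_window`) tracks slow drift but collapses once
valleys occupy more than half a window — at 100–150 RBC/s with a 3 ms
transit that happens in a third of 30-ms windows — so the constant
(single-threshold-line) baseline is the default for 0.6-s traces, which
drift negligibly.

Noise scale: 1.4826 × the one-sided median absolute deviation of the
non-negative baseline residuals. Valleys only pull residuals downward, so
the upper half-distribution estimates the shot-noise scale uncontaminated
up to 50% valley occupancy. For noise-free traces (σ̂ = 0) the threshold
falls back to halfway down the dynamic range; a constant trace then counts
zero valleys.

Threshold: baseline − 3σ̂. Maximal below-threshold runs are valleys; runs
separated by a single above-threshold sample are merged (debounce 1), and
runs shorter than 2 samples (600 µs) are discarded as shot-noise dips.

Two flux numbers are reported per trace:

* `flux_rbc_per_s` — the raw definition, valley count / 0.6 s. For Poisson
  arrivals at rate λ with transit time w its expectation is λ·e^(−λw): at
  60 RBC/s the raw count undercounts by ~17%, at 150 RBC/s by ~36%,
  because transits closer than w merge into one valley.
* `flux_corrected_rbc_per_s` — raw/(1 − occupancy), where occupancy is the
  fraction of samples inside counted valleys. Since the expected occupancy
  is 1 − e^(−λw), the ratio recovers λ exactly in expectation without
  knowing w. Downstream summaries use this estimate by default
  (`FluxParams.use_corrected`); measured recovery is within ~6% of ground
  truth across 10–150 RBC/s. Above ~330 RBC/s (λw > 1 at 3 ms transit) no
  count-based estimator is informative; traces with > 95% of samples below
  threshold are flagged unresolvable.

## Histology densitometry

Per channel, one intensity threshold is determined for an entire batch —
Otsu's histogram criterion on the brightest MIP of the batch (mirroring
acquisition settings being fixed on one of the brightest slices) — and
applied identically to every image; per-image thresholds are a contract
violation. Percent area = 100 × positive/total pixels, per cortical layer
band (depth axis mapped to µm via the pixel size, pial surface at the top
row by default) and globally. PA is monotone non-increasing in the
threshold, and the global PA is the pixel-count-weighted mean of the layer
PAs. The exact histogram rule used in any given lab is rarely recoverable;
Otsu-on-the-brightest is this package's documented default and is
configurable via explicit per-channel thresholds.

## Synthetic forward models

The generators emulate the acquisition at the level the analysis sees:

* **Decays** — expected bin counts A·exp(−t/τ(pO2)) + C at the bin-start
  times, scaled so the expected total equals the photon budget exactly,
  with independent Poisson bin noise. The constant background C defaults
  to 0.5% of the amplitude. The default photon budget of 1e5 per
  repetition gives a per-location pO2 noise of well under 1 mmHg after
  averaging, small against the configured 6 mmHg between-vessel spread —
  no printed count rate constrains this, so it is a documented choice.
* **Traces** — Poisson-process RBC arrivals; each arrival depresses the
  signal toward (1 − 0.9)·baseline for a 3 ms transit (≈10 samples);
  overlaps merge into wider, never deeper, valleys; per-sample expectation
  weights partial coverage; Poisson noise on top. Transit time and valley
  depth are not observable from published summaries; 3 ms and 0.9 make
  typical capillary fluxes (30–120 RBC/s) resolvable. Arrival times ship
  as ground truth with every trace.
* **Cohorts** — two cohorts (WT, AD) × three layers × three vessel classes
  with configurable baseline pO2 means, a between-vessel SD (default
  6 mmHg), additive per-day pO2 offsets modelling the inflammatory
  stimulus, and per-capillary flux ~ N(62, 18²) RBC/s. Defaults are seeded
  from reported awake-mouse cohort means where available (layer-IV
  arteriolar pO2 69.33/80.79 mmHg for WT/AD, WT capillary ≈48.6 mmHg, and
  day-7 offsets −8/−14 mmHg sized so the layer-IV capillary ΔSO2 lands
  near −13%/−23%); the remaining values are realistic interpolations.
  They are configuration inputs, never asserted as results. Penetrating
  vessels keep their 50-µm baseline on the correct side of 66 mmHg by
  truncated sampling, and the same vessel ids recur across days 0/7/14.
  Animal counts default to 7 WT / 8 AD.
* **IF stacks** — disk-shaped blobs (radius ~ N(6, 2²) px, clipped ≥ 2) at
  bright level 200 on Poisson background level 20, painted until the 2-D
  union mask reaches the target positive-area fraction (the final blob may
  overshoot by at most one blob area; the achieved fraction and exact mask
  are recorded as truth), 11 z-planes at 3.96 µm.

Identical (config, seed) pairs are bitwise reproducible everywhere.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: optical scattering and depth-dependent SNR loss,
motion artifacts beyond outlier-decay totals, probe photobleaching, flow
pulsatility and non-Poisson RBC spacing, spatially correlated oxygen
fields, and realistic cell morphology in IF images. Recovery results on
synthetic cohorts validate the estimators' correctness and calibration,
not their robustness to those effects.

## Problem sizes and runtime

The test suite and the acceptance script run simulation studies at sizes
chosen to keep the full run in the low minutes on one CPU while leaving
Monte-Carlo error well below the asserted tolerances: 500 seeds for
Poisson lifetime recovery (median within 1% at 1e5 photons), 1e4 null sets
for the Grubbs size, 1000 constructed traces for the valley-counting
oracle, 200 seeds per rate at 10/30/60/100/150 RBC/s for flux recovery,
and cohorts of 2–4 animals per group with 2 vessels per class for the
end-to-end identities and ΔSO2 recovery. Full-scale cohorts (7–8 animals,
default vessel counts) run in tens of seconds via `plimox run`.

## Known limitations

* The linear Stern–Volmer form is a modelling choice; strongly nonlinear
  probe calibrations require replacing the conversion functions.
* The pile-up correction assumes memoryless arrivals and a uniform transit
  time; strongly pulsatile or stalled flow violates both.
* Densitometry is intensity-threshold-based only: no cell segmentation,
  counting or colocalization.
* Inferential statistics (t-tests, ANOVA families) are intentionally out
  of scope; the tidy CSV outputs are arranged for direct consumption by
  any statistics package.
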