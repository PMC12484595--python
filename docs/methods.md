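# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions.

## Sound metrics

Raw hydrophone amplitudes are calibrated as `10^(|s|/20)` µPa per raw unit,
where `s` is the hydrophone sensitivity magnitude in dB re 1 µPa (the
standard convention for an element quoted as, e.g., 205 dB re 1 µPa);
pressures are held in Pa internally and the 120 dB Pa→µPa term enters only
at the dB stage.  Broadband SEL uses the rectangular-window energy sum
`10·log10(Σ p²Δt)` re 1 µPa²s with a 1 s reference duration; windows are
contiguous, non-overlapping and start at the recording start (alignment is
a free choice; no tapering is applied, so window energies partition total
energy exactly).  Band-limiting to 10 Hz–20 kHz uses a 4th-order
Butterworth filter run forward-backward (zero phase, order effectively
doubled), so peak-to-peak readings are not distorted by phase lag.
Peak-to-peak pressure is computed on the band-limited series
(`p2p_on_filtered: true` in the config); band-limiting also removes DC, so
p2p is offset-invariant.  An all-zero window returns −inf SEL as a sentinel
rather than raising, so recording gaps survive batch processing.  No shot
detection or per-shot SEL is attempted: with 10 s windows and a ~10.7 s
firing interval some windows legitimately contain no shot.

## Synthetic approach and airgun recording

The vessel track is uniform-speed linear approach (default 4.5 knots =
2.315 m/s from 10 km), distance reflecting at the pass point.  The firing
interval (default 10.7 s) is an independent parameter of the scenario: it
is deliberately not derived from the 50 m shot spacing and the vessel
speed, which would give ~21.6 s; the observed interval is what the
generator emulates.

The recording is Gaussian white noise band-limited to the analysis band and
rescaled so the *expected in-band* SEL of one 10 s window equals the noise
floor (default 158 dB re 1 µPa²s — the research-vessel noise level the
study design implies).  Each shot adds an exponentially damped sinusoid
(60 Hz carrier, 50 ms e-folding time: energy concentrated below ~100 Hz,
where airgun arrays emit most of theirs) whose received energy follows
`source_sel_at_1m − k·log10 r` with spherical spreading `k = 20` by default;
frequency-dependent absorption is omitted (negligible below 100 Hz within
10 km).  The default source level of 233 dB re 1 µPa²s at 1 m places the
shot-noise crossover near 6 km, the qualitative behavior expected of a full
array against a ship-noise floor.  The exact pulse shape is otherwise a
free choice: only SEL/p2p recovery is validated, not waveform fidelity.
The shot log records per-window ground truth (expected noise energy plus
realized pulse energy, realized p2p), which the recovery tests score
against.

## Echogram and vertical indicators

The scattering layer is Gaussian in depth (default mean 25 m, sd 5 m —
a mid-column layer such as one hugging the pycnocline) with core Sv
−75 dB re 1 m⁻¹, observed on a 2 m × 2 s grid from the surface down to 5 m
above the 70 m seafloor (the transducer position).  Cells get multiplicative
lognormal noise with a 3 dB log-domain sd.  A planted "response" perturbs
the layer mean and/or variance linearly in source distance (m per km and
m² per km); the generator returns the continuous-limit truth (CM = mean,
I = variance) per time bin.  Sampling a Gaussian at 2 m bin centers makes
the discrete moments match the continuous ones to well under 1%, so layer
recovery is limited by the surface/bottom truncation, not the grid.

Indicators are computed on linear sv (echo-integration convention: energy,
not dB, is additive).  Exclusion masks (default: above 5 m, within 5 m of
the bottom edge) retain the underlying values; time bins with zero unmasked
energy yield NaN sentinels and are dropped from fits rather than imputed.
Depth is positive downward, bins half-open with centers reported.  Inertia
is reported in m² (the second central moment of depth); distance fits use
OLS — a Gaussian identity-link general linear model with one continuous
covariate — on per-time-bin indicators by default, with 1 km distance
binning (configurable; width is a reporting choice, not part of the model)
available for summaries up to 9 km.

## Stain imaging

Synthetic photographs place non-overlapping ellipses (semi-axes 8–16 px)
on a light background (gray level 235).  Live bodies draw red-channel
saturation from N(0.75, 0.06), dead from N(0.15, 0.05), both at body
brightness 0.55 — stochastically separated classes, mimicking strong vital
staining against weak diffusive uptake.  Gaussian pixel noise (sd 6 of 255)
is the default.  The generator does not emulate out-of-focus blur, touching
animals, debris, scale bars or taxon diversity, so classifier accuracies on
synthetic batches bound only threshold logic and color separation, not
real-photograph segmentation difficulty.

The classifier segments dark-on-light foreground with an automatic Otsu
threshold, labels 8-connected components within area bounds (40–50 000 px),
and computes each region's stain fraction in an HSV window: hue in
[320°, 40°] (circular red band), saturation ≥ 0.35, value in [0.10, 0.95].
Hue/saturation thresholds make calls invariant to uniform brightness
scaling within the value window.  The live call is
`stain_fraction ≥ 0.25`, boundary inclusive.  Touching organisms are not
split (no watershed): merged clumps surface as area outliers for manual
audit, and the overlay image paints stain-window pixels vivid green.
Thresholds are explicit configuration; the defaults were chosen on the
synthetic fixtures and a known-dead calibration batch (≤ 5% live calls),
and classifications are stable under ±30% stain-intensity scaling.

## Bag and net mortality

Bag mortality is a two-stage process per individual: immediate death at
day 0 with probability p₀, then a constant daily hazard h for each survivor
(geometric survival — matching daily inspection), giving the closed-form
expected cumulative proportion dead `1 − (1−p₀)(1−h)^d` at day d.  The
default scenario uses the field design's arm sizes (bags of 10: 12 control,
18 handling control, 9 far exposure, 36 close exposure), day-0
probabilities 2 / 2 / 2.3 / 5.4% and hazards solved so expected day-7
mortality is 12.7 / 11.7 / 22.3 / 25.1%.  The control day-0 value (2%) is
a choice — only the exposed arms' immediate mortalities are constrained by
the emulated observations — set between the far-exposure value and zero.
Net-haul dead counts are beta-binomial (intra-class correlation 0.05,
haul size 100) around a distance curve, flat at 15% by default: high,
trendless background mortality is the field situation being emulated.

The bag GLM is binomial with logit link, response encoded as the per-bag-day
proportion with bag size as variance weight (the faithful binomial weighting
when 10- and 50-animal bags mix), day continuous by default (factor coding
available), treatment dummy-coded against `control`.  Two treatment tests
are exposed: per-treatment Wald contrasts (with day continuous plus
interaction, the main-effect contrast is the day-0 log-odds difference) and
a likelihood-ratio test of *all* treatment terms, which is the test used for
the cumulative "treatment effect" headline — a delayed effect lives mostly
in the interaction, which the main-effect contrast alone cannot see.
Complete separation (an arm with no deaths or no survivors) is detected
before fitting and triggers a continuity-corrected fallback (+0.5 dead and
+0.5 alive per bag-day), flagged on the results object.

A deliberate limitation, carried in every summary: cumulative bag-day rows
of one bag are serially correlated, and the plain GLM treats them as
independent — the model is implemented as used in the field, without
random effects.  Consequently the cumulative model's treatment test is not
α-calibrated under the generator's null, and the null-calibration utilities
(`calibrate_null`, the acceptance checks) use the immediate (day-0 only)
variant, the one model whose independence assumption the generated data
satisfy.  Its Wald contrast rejects at ≈ 4–5% under identical arms.

Rank tests use exact permutation enumeration — all n! orderings for
Spearman at n ≤ 9, all C(n₁+n₂, n₁) assignments for Mann-Whitney at
combined n ≤ 18, both on mid-ranks so ties are handled — and tie-corrected
large-sample approximations beyond that.  Two-sided p-values throughout;
α = 0.05; no multiple-testing correction is applied (none is part of the
emulated analysis), which reports note.

## Power analysis

`power_analysis` is Monte-Carlo: simulate the scenario's full design,
fit the chosen model variant, count rejections at α, report a normal 95%
CI.  Under the calibrated effects and the default arm sizes it documents
the design's sensitivity; there is no external value it must match.

## Pipeline, determinism, problem sizes

One top-level seed derives all per-stage scenario seeds; generators take
seeds as explicit fields and never touch global random state, so a config
reproduces a run byte-for-byte (`report.json` excludes wall time for this
reason).  The default pipeline synthesizes 60 s of 48 kHz audio per run
(enough for six analysis windows) while the track, echogram and experiment
designs span the full ~10 km approach; full-approach audio (~72 min) is
supported but is not the default example size.  Repeated-seed studies
(null calibration, qualitative-pattern rates) use the lightweight
`headline_pattern` path, which skips audio and image synthesis since
neither enters the four headline statistics.

## Known limitations

- No physical airgun-array signature (ghosting, directivity, notional
  sources) and no propagation modelling beyond single-exponent geometric
  spreading.
- The echo module starts from gridded Sv; raw-echogram processing,
  calibration and species separation are out of scope.
- Stain thresholds are per-batch configuration, not learned; scale-bar
  detection is manual.
- Bag-level repeated-measures correlation is unmodelled in the GLM (see
  above); a mixed-effects extension would be the natural next step.
- The qualitative headline pattern is stochastic: with the calibrated
  effect sizes the immediate-mortality test genuinely rejects in roughly a
  third of simulated studies (the planted immediate effect is small but
  real), so the full four-part pattern appears in a majority — not the
  totality — of runs.
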