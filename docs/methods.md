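# Methods

This note documents the models implemented in `actisleep`, the choices made
where the published record is ambiguous, and what the synthetic evaluation
does and does not demonstrate.

## Signal chain

**Epoch grid.** All scoring happens on non-overlapping 30-s epochs with
half-open windows `[t, t + 30 s)`, anchored at the PSG hypnogram start.
Trailing partial epochs and windows are dropped, never padded, in I/O;
zero-padding exists only inside windowed classifiers. Recordings with
internal gaps (> 2× the median sample interval) are rejected rather than
imputed: the toolkit defines no imputation model, and silently filled gaps
would corrupt counts and angles downstream.

**Downsampling.** Raw acceleration (wrist-worn, in g, gravity included,
default 85.7 Hz) is brought to 40 Hz by taking the arithmetic mean within
fixed 25-ms half-open windows.

**Activity counts.** Counts follow the published reverse-engineering of the
legacy ActiGraph chain: polyphase anti-aliased resampling from 40 Hz to the
filter's native 30 Hz; a fixed band-pass filter; rectification; saturation
at 2.13 g; a dead band below 0.068 g; 8-bit quantization (2.13/128 g per
unit); decimation to 10 Hz; per-epoch summation. The band-pass stage is a
3rd-order Butterworth with 0.25–2.5 Hz edges designed at 30 Hz — a clean,
exactly-DC-blocking stand-in for the legacy analog band — applied with
DC-steady initial conditions (`lfilter_zi` scaled by the first sample) so a
constant gravity vector produces zero counts from the very first epoch.
Consequences that the tests rely on:

* the chain up to quantization is linear in input amplitude, so per-epoch
  counts are non-decreasing in oscillation amplitude and reach a hard
  plateau (300 samples × 128 units = 38,400 per epoch) once every retained
  sample clips;
* counts are invariant to static orientation changes and to adding a
  constant offset;
* the filter's causal tail decays below the dead band in ≈ 1.3 s, so
  activity separated by ≥ 2 s of quiet from an epoch boundary cannot leak
  counts into the neighbouring epoch. The first epoch is computed on
  zero-padded history and is flagged (`warmup_epochs`).

Absolute count magnitudes are **not** calibrated against any proprietary
implementation (none is available to compare against); all documented
properties are scale-robust, but coefficients tuned on device counts
(Cole–Kripke, Sadeh, Oakley, Sazonov) will sit at a different operating
point on this scale — see "Synthetic evaluation" below. The
`compute_counts(backend="agcounts")` switch delegates to the open-source
reference package when installed, for cross-validation.

**Axis combination.** The literature does not state which axis or
combination fed the legacy algorithms; the default is the vector magnitude
`sqrt(cx² + cy² + cz²)`, configurable per run and recorded in the run
manifest, since count provenance is the chief generalization hazard for
count-based scoring. `(cx² + cy² + cz²)^(1/6)` is provided for
count-sequence models trained on compressively combined counts.

## Classifiers

All classifiers emit exactly one label per 30-s epoch for any input length.
Out-of-range window epochs read as zero counts. Models with a 1-minute
trained basis (Cole–Kripke, Oakley, Sadeh) aggregate 30-s counts by
pairwise sums, classify minutes, and broadcast each decision back to its two
30-s epochs — preserving each algorithm's native basis while honouring the
30-s comparison grid.

**Coefficient presets** live in `data/presets.yaml`, versioned and cited,
never hard-coded: Cole–Kripke (1992 reweighting: scale 0.001, weights
106/54/58/76/230/74/67 on minute offsets −4…+2, sleep when the score < 1);
Oakley (symmetric 0.04/0.2/1/0.2/0.04 window, device threshold with
medium-sensitivity default 40, sleep when score ≤ threshold — the exact
threshold used in past comparisons is rarely reported, so it is
configurable); Sadeh (PS = 7.601 − 0.065·MW5 − 1.08·NAT − 0.056·SD6 −
0.703·LG with the NAT band [50, 100) counts/min; threshold 0 by default
with the −4 variant in circulation selectable); Sazonov (logistic model on
trailing-window maxima over 1–5 epochs, intercept 1.727, weights −0.256,
−0.154, −0.136, −0.140, −0.176, sleep when P ≥ 0.5, as propagated by the
published benchmark implementation of the infant-trained original). Sadeh's
SD6 uses the population standard deviation of the current plus preceding
five minutes.

**van Hees z-angle heuristic.** Per-axis 5-s centred rolling medians, then
the forearm elevation angle `atan(z / sqrt(x² + y²))` in degrees, averaged
over consecutive 5-s blocks. Maximal runs of blocks whose successive
absolute changes all stay below 5°, lasting ≥ 5 min, are sleep; block labels
are resampled to epochs by majority with ties going to wake (conservative
toward detecting disturbance). An all-zero acceleration vector has no
defined orientation; the angle is reported as 0° with a warning.

**Random forest.** A seeded scikit-learn forest over per-epoch summaries
(per-axis mean/SD/min/max, vector-magnitude and z-angle mean/SD) with ±2
epochs of lag/lead context, zero-padded at the record edges. This is a
training harness in the spirit of the published raw-acceleration forests,
not a reproduction of any published trained model. The pipeline trains it
leave-one-subject-out.

## Webster rescoring

Only sleep → wake changes are possible. The canonical rule set: after ≥ 4 /
10 / 15 min of wake, the next 1 / 3 / 4 min of the immediately following
sleep are rescored wake; sleep bouts ≤ 6 min flanked by ≥ 10 min of wake on
both sides, and ≤ 10 min flanked by ≥ 20 min, become wake. Rules are
applied sequentially in listed order on the progressively updated sequence
(order configurable), each rule reading the run structure of its own input.
Bouts at the record edge lack a flank and are never rescored by the
surrounded rules. Two consequences: total scored sleep is non-increasing
under any rule subset, hence against any fixed reference sensitivity can
only fall and specificity only rise; and *iterated* application cascades —
a wake run lengthened by rescoring re-qualifies next time — so idempotence
does not hold and a fixed point is only guaranteed within a sleep-count
budget (tested as such). The pipeline applies rescoring to the legacy count
algorithms by default, where it was historically intended.

## Endpoints and validation

Sleep is the positive class: TP = both PSG and algorithm say sleep.
Sensitivity, specificity, precision and accuracy are percentages; F1 is the
harmonic mean of precision and sensitivity. Metrics with zero denominators
are flagged undefined and excluded pairwise from cohort means (with the
exclusion count reported), never silently zeroed; the one principled
exception is F1 = 0 whenever sensitivity is 0, which keeps the all-wake
baseline's F1 well-defined.

Endpoints: onset is the first sleep epoch by default (a "first of k
consecutive" rule is available, since sleep-onset definitions vary);
offset is the last sleep epoch; WASO sums wake between them; TST is all
scored sleep; SE is sleep as a percentage of the annotated period (the
denominator is a parameter because annotation conventions differ). A night
with no scored sleep has TST 0, SE 0 and undefined WASO/onset.

Cohort statistics are computed per subject and then averaged (unweighted
mean, population SD — so a single-subject cohort reports SD 0), which is
what makes endpoint-level Bland–Altman analysis possible. Bland–Altman uses
differences d = algorithm − PSG: ME = mean(d); RMSE = sqrt(mean(d²)) — the
root of the mean *squared differences*, not of the squared mean error,
which would collapse to |ME|; limits of agreement ME ± 1.96 × sample SD
(ddof = 1) of d, with their width reported. Pearson r is undefined under
zero variance, dispersion terms under n < 2. The selection rule retains
algorithms with cohort-mean sensitivity ≥ 75% and specificity ≥ 45%,
reflecting that specificity (wake detection) is the scarce commodity in
actigraphy.

## Synthetic evaluation

The generator emulates a single-night PSG cohort: 28 subjects, 8-h nights,
alternating bouts starting in wake. Sleep bouts are floor-shifted geometric
(minimum 5 min, mean 35 min), wake bouts geometric (mean 15 min) — the
means give ≈ 70% sleep, a disturbed-patient regime; the 5-min sleep-bout
floor exists because a sleep bout shorter than the posture heuristic's
5-min stillness window is invisible to *any* such detector, so the
end-to-end separability guarantee would otherwise be ill-posed. The
parameterization keeps the configured means exactly. Wake epochs carry
0.5 g band-limited (0.5–3 Hz, inside the count passband by construction)
movement with per-5-s-block orientation dither and a posture shift at every
wake-bout start and every 2 min within a bout; sleep is static at the last
adopted posture with 10 mg Gaussian sensor noise (below the count dead
band), plus — with per-epoch probability `sleep_residual_movement_prob`
(default 0.05) — a 20-s movement burst emulating disturbed sleepers.
Movement stops 2 s before each epoch boundary so filter tails stay in their
epoch, and a wake bout settles on its base posture before sleep begins, so
the wake → sleep boundary is step-free. All randomness flows from one
master seed through per-subject seed sequences.

What passing tests demonstrate: the full chain is wired correctly — clean
wake/sleep structure is recovered at ≥ 99% epoch accuracy by the posture
heuristic and by count thresholding, estimated WASO rises monotonically
with injected sleep disturbance, and the analytic endpoints stored with
every generated night match the endpoint computation exactly. What they do
not demonstrate: clinical accuracy. Synthetic sleep is perfectly still and
synthetic counts are larger than the device counts the legacy coefficients
were fitted to, so Cole–Kripke/Sadeh/Oakley/Sazonov run far on the
wake-biased side of their operating point here (near-perfect specificity,
low sensitivity) — the opposite of their clinical profile. Algorithm
rankings on this generator say nothing about rankings on patients.

Numerical details worth knowing: geometric bout statistics have SD ≈ mean,
so empirical bout-mean checks use a 100,000-epoch night (~700 bouts) for a
5% tolerance to be meaningful; count saturation tests exclude the warm-up
epoch; van Hees ties resolve to wake; the pipeline's problem sizes in tests
(2–3 subjects, 1–2-h nights; one 8-h night for separability; 20 seeds × 4
disturbance levels at 2 h for the WASO trend) were chosen to keep the suite
fast while leaving every property overdetermined.

## Known limitations

* No proprietary-count calibration: agreement with any vendor's counts is
  unverified; relative properties, not absolute magnitudes, are guaranteed.
* No EDF/biosignal PSG parsing, no device binary formats, no
  autocalibration — inputs are pre-calibrated g values in delimited text.
* Binary sleep/wake only; no staging.
* The synthetic generator models neither realistic sleep architecture nor
  circadian structure, non-wear, or multi-night recordings.
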