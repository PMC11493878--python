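# Methods

This note documents the models behind `plaslab`, the defaults that matter,
what the synthetic data do and do not emulate, and the numerical choices
made where the design was genuinely open.

## Study design being modeled

A multi-night closed-loop acoustic stimulation study: each participant
sleeps a baseline night (the detection algorithm runs but only logs sham
markers) followed by three consecutive stimulation nights E1–E3 (a 50-ms
pink-noise burst is presented at each predicted slow-wave peak). Memory is
probed by a 40-item cued-recall task at sessions t0 (pre-intervention
baseline) through t7 (3-month follow-up), with corrective feedback during
t1–t4 acting as additional learning runs. Blood plasma Aβ42/Aβ40 ratios are
taken after the baseline night and after E3; the post-minus-pre difference
is the amyloid-dynamics outcome (more positive = more amyloid moved into the
bloodstream, interpreted as beneficial clearance). Cohorts contain a healthy
group (HC) and a cognitively impaired group (CI) defined by a cognitive
screening cut-off.

## Synthetic data generator (`synth`)

**Signal model.** Recordings are simulated directly at the 200-Hz analysis
rate (real studies record faster and downsample; simulating at the analysis
rate avoids a pointless resample, and `preprocess.downsample` is exercised
separately on higher-rate inputs). Channels sit on a Fibonacci spiral over
the head sphere — high-density nets publish no canonical coordinates for
this purpose — with the channels nearest the canonical Fz/Cz directions
renamed to those labels. The background is 1/f (pink) noise, default RMS
15 µV per channel, independent across channels.

**Slow waves.** Events are placed in N2/N3 epochs by a Poisson process at
the profile's density (defaults: HC 8/min, CI 5/min of deep sleep; the
impaired group's sparser, smaller waves are qualitative facts without
published numbers, so both are tunable). The kernel is one 0.9-Hz biphasic
cycle built from raised-cosine segments with a deliberately *asymmetric*
shape — 45% of the cycle descending into the trough, 25% rising steeply to
the positive peak, 30% returning to baseline. The steep up-slope matches
real slow-wave morphology and is load-bearing: with a symmetric cycle the
online criterion would cross ~350 ms before the peak, outside the detector's
0–200 ms delay-calibration range. Amplitudes are drawn from N(75, 15²) µV
(HC) or N(50, 15²) µV (CI) at Fz, with a Gaussian frontal-maximal scalp map.
Spindles are 12–16 Hz Gaussian-windowed bursts in N2 with a centroparietal
map. The hypnogram repeats fixed-proportion stage blocks (default 32-min
cycle: W 4, N1 4, N2 10, N3 6, N2 4, REM 4 min) — the simplest structure
that supplies the N2/N3 analysis mask; no Markov dynamics.

**Evoked response.** Each real stimulation adds a damped 1-Hz cosine
windowed to 0.25–1.75 s post-marker: a negative deflection centered in
0.5–1 s followed by a positive frontal peak in 1–1.5 s. The kernel is
normalized so that the mean Fz voltage over 1–1.5 s equals
`responsiveness × night_gain × evoked_peak_uv` (default 8 µV per unit),
making the ERP response score linear in the latent responsiveness by
construction. Night gains encode the groups' temporal signature: constant
(1, 1, 1) for HC, ramping (0.4, 0.7, 1.0) for CI — the delayed
electrophysiological response of the impaired group.

**Behavior and biomarker.** Memory scores follow a saturating learning curve
through the feedback sessions t1–t4 (asymptotes 32 HC / 22 CI items,
rate 0.55 per session), then decay without feedback (−1, −4, −14 items by
t5, t6, t7). The stimulation effect (`memory_slope`, default 0.5 items/µV)
is expressed at t5–t6 for HC but only at t7 for CI, reproducing the delayed
memory benefit. The Aβ42/40 change is `abeta_slope × response score` plus
N(0, 0.003) noise, with slope 0 for HC and 8×10⁻⁴ per µV for CI (sized to
make the CI association detectable at n = 16 while the HC association stays
null, as in the study pattern). Scores are integer-rounded and clipped to
[0, 40]; ratios clipped to (0, 1).

**What is not emulated.** K-complexes, arousals, REM phasic events,
circadian structure, realistic artifact topographies, volume-conduction
covariance between channels, and questionnaire instruments. Passing tests
therefore demonstrate correctness of the *analysis* under the stated
generative assumptions, not performance on recorded sleep EEG.

## Online detector (`detector`)

The criterion follows the template algorithm: over the trailing 120-ms
window, the average sign of the first derivative of both the mean frontal
voltage and the topographic template correlation must exceed 0.75. Choices
within that rule:

* **Per-series criterion.** The sign-average of *each* series must exceed
  the threshold (the stricter reading of "the average of the sign … of
  both"); it is monotone in either interpretation.
* **Correlation convention.** Pearson correlation across channels between
  the instantaneous scalp map and the template, yielding a correlation time
  series ("topographic correlation"); correlating time courses instead was
  rejected as inconsistent with that term.
* **Smoothing.** A causal 40-ms moving average (`smooth_ms`) is applied to
  both series before differentiation. Real acquisition chains are
  bandlimited; on raw broadband samples the sign of the derivative is the
  sign of the noise and the criterion can never fire. The stage preserves
  causality and its small lag is absorbed by delay calibration.
* **Refractory lockout**, default 2.5 s, covering the post-stimulus analysis
  window so the detector cannot retrigger on the evoked second peak.
* **Evaluation every sample**; windows are half-open (t − 120 ms, t].
* **Template.** Published template values are not available; the stand-in is
  the cosine of the angle between each electrode and the Fz direction
  (frontal-positive, posterior-negative), unit-normalized, with the nearest
  17 channels to Fz as the frontal voltage set. It is configurable.
* **Delay calibration** returns the median criterion-crossing→true-peak lead
  over detected events, clipped to [0, 200] ms (default 50 ms).

A fully deterministic benchmark (`synth.benchmark_recording`) superimposes
template-matched events on a *static* background map orthogonalized to the
event topography with zero frontal mean: the topographic correlation then
sweeps smoothly through each rise while the voltage comes from the events
alone. With pure single-component signals the Pearson correlation is
piecewise constant and the criterion cannot fire at all — background
structure is essential to the algorithm, on synthetic and real data alike.

## Preprocessing (`preprocess`)

Downsampling uses zero-phase FIR decimation (polyphase resampling for
non-integer ratios); event and hypnogram timestamps are seconds-based and
untouched. Artifact rejection is a deliberately simplified stand-in for a
full robust-preprocessing pipeline: flatline channels are removed; samples
violating amplitude (250 µV), jump (80 µV/sample), or high-frequency power
(z > 6 above 25 Hz) limits are masked with 250-ms padding; channels masked
beyond 30% become bad and the mask is recomputed from good channels.
Epochs overlapping any masked sample are dropped (whether artifact windows
were excluded before or after event epoching is not specified anywhere; the
conservative choice drops them before).

## ERP / ERSP analysis (`erp`, `ersp`)

Epochs span −1.5…3 s inclusive; baseline correction subtracts each
trial-channel's whole-epoch mean. Cluster permutation follows the
Maris–Oostenveld scheme: bin-wise pooled-variance t, cluster-forming
threshold at the point-wise two-tailed .05 t quantile, cluster mass = sum of
t over members, adjacency = orthogonal grid neighbors within a channel plus
a spherical-distance channel graph at the same bin, null distribution = max
cluster mass over random relabelings of the observation labels (trials
within participant, or participants at the group level), p = (1 + r)/(n_perm
+ 1). Degenerate-variance bins never enter cluster formation. Default
n_perm = 1000 with a recorded seed.

Morlet cycle counts increase linearly from 1.25 at 0.5 Hz to 7 at 20 Hz.
The low end is dictated by the epoch: the wavelet support is 10·σ_t =
10·cycles/(2πf), and only ~1.4 cycles fit a 4.5-s epoch at 0.5 Hz; edge
bins inside half a wavelet of the epoch boundary are flagged. dB
normalization divides by the mean power in 2–2.5 s (the quietest window of
the epoch). Band response scores use the median over the band's
channels × frequencies × window, differenced against the baseline night and
weighted by stimulation counts; the default window is the induced-peak
window 0.75–1.5 s, except beta which is scored pre-stimulus (−1.5–0 s),
where its suppression is expected. The summed-activity statistic restricts
the significant-cluster mask to 0–2.5 s × 0–16 Hz (effectively 0.5–16 Hz on
the computed grid), takes |dB| of the experimental/baseline power ratio per
bin, and excludes bins above the participant-night mean + 1.5 SD (sample
SD; one-sided upper cutoff, since the values are already absolute — a
`symmetric` switch restores two-sided pruning).

## Cohort statistics (`stats`)

Student (pooled-variance) t-tests throughout, matching df = n₁ + n₂ − 2;
summary-statistic and raw-data entry points agree to machine precision.
Gender contrasts use the Yates-corrected chi-square. Sleep-architecture
difference scores collapse the experimental nights (mean(E1..E3) − BL) per
participant; Holm–Bonferroni families are one per test battery (all
between-group tests; all within-group tests per group). Regressions are OLS
with overall F, adjusted R², and model p; covariate variants (age, gender as
a binary indicator, uncentered) are fitted alongside and attached for
comparison. Zero-variance contrasts are reported as t = 0, p = 1 rather than
errors: degenerate data carry no evidence.

## Problem sizes used in testing

The test-suite and acceptance-script study sizes are chosen as the smallest
that make the statistical checks meaningful: detection benchmarks use a
~20-minute 32-channel night; permutation-test calibration runs 500 null
datasets on an 8-channel × 50-time-bin (× 10-frequency-bin) grid with 200
permutations; parameter-recovery and null-calibration use 200–500 replicate
34-participant cohorts generated at the latent level (profile →
response score → outcomes), since the regression properties do not depend
on the EEG synthesis in between; the full closed-loop EEG chain is verified
end-to-end on short nights and small cohorts. The delayed-response pattern
is likewise checked on summed activity computed from compact
time–frequency maps driven by the profiles' night gains, using the same
`summed_activity` and trend-test code paths as the full chain.

## Known limitations

* The detector's operating characteristics on real sleep EEG will differ
  from the synthetic benchmarks; no published operating characteristics
  exist to validate against.
* The template map, electrode subsets ("17 around Fz", "13 around Cz"), and
  channel adjacency are geometric stand-ins parameterized on the spiral
  layout; real montages should supply their own.
* Group-level permutation tests exchange whole participants; mixed-effects
  alternatives are out of scope.
* EDF export is not provided (no writer dependency); recordings round-trip
  via npz + JSON, and all event/marker/hypnogram/cohort interchange is
  plain text. EDF import is available through mne.
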