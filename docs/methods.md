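# Methods

This note documents the models, numerical choices and limitations behind
`vwm`, in the spirit of the methods documentation of mature scientific
packages. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task protocol

Task blocks hold 21 stimuli. A 30% target rate over 21 items is not an
integer, so the target count is fixed at **6 per block** (28.6%) — the
closest integer below 30% — keeping blocks exactly comparable; it is a
parameter of `generate_block`. Target placement: for level L ∈ {1, 2}, six
admissible positions (index ≥ L) are drawn and the letter from position
i−L is copied there; remaining positions are filled avoiding accidental
lag-L repeats, which guarantees the exact count. The probe letter X appears
only in 0-back blocks (and there only as a target); the seven consonants
never include it. The first L positions of a block are never targets by
construction.

Timing: stimulus duration 500 ms; the interstimulus interval is
offset-to-next-onset (audio 2500 ms, video 3000 ms; the passive baseline
block uses 3000 ms in both modalities), so onset asynchrony is
duration + ISI. Reaction times are stored relative to stimulus offset, and
the simulator and the scorer share this convention. Every trial expects a
forced-choice response; trials without one are scored incorrect. With zero
correct responses in a cell, mean RT and IES are reported missing with a
warning rather than fabricated.

## Synthetic cohort

The generator emulates the statistical structure of an 11-child cohort, not
any real recording. Signals are sums of:

* **1/f^β background** (β = 1 by default) plus white sensor noise, each
  trace independently normalized so the 1/f part has a 9 µV RMS within
  1–45 Hz and the white part 2 µV. Channels are independent — no volume
  conduction or correlated sources.
* **Band-limited oscillations**: amplitude-jittered sinusoids whose phase
  is re-randomized each stimulus interval — the simplest process with
  controllable band power (a sinusoid of amplitude A contributes A²/2 µV²).
  Theta (IAF−4 Hz) is weighted toward frontal/midline/left sites and its
  power scales as `theta_load_gain^level` (default gain 1.25 per load step,
  between-subject SD 0.25); alpha (IAF) is posterior and strong (200 µV²)
  only in the 60 s eyes-closed segment; beta power scales with a
  per-condition engagement level; parietal gamma follows per-cell gains
  (audio 1.22/1.03/0.75 across loads, video flat) producing a
  load-by-modality interaction without a modality main effect.
* **Blinks**: half-cosine pulses (400 ms, ~150 µV at Fpz) scaled by a fixed
  anterior-to-posterior gain vector, at a Poisson rate (default 8/min) —
  exactly identifiable by regression, which is the point.
* **Artifact injections** (optional, logged): amplitude spikes, square
  steps and flattened channels in continuous recordings; epoch-level sets
  (`make_artifact_epochs`) additionally include pure slope ramps
  (±45 µV/s, sub-threshold amplitude) and are band-limited to 1–45 Hz
  first, matching what the detector sees in the pipeline, where rejection
  runs after filtering. Epoch-long linear drifts are essentially removed
  by a 1 Hz zero-phase high-pass, which is why recording-level injections
  use the spike/step/flat menu.

Behavior: correctness is Bernoulli with per-cell accuracies (defaults:
audio 0.970/0.876/0.870, video 0.909/0.833/0.740 across loads); RTs are
lognormal (σ_log = 0.28) around
`rt_base + 130·level + 130·[audio] − 150·engagement`, with engagement
rising 0.4 z per load level plus a 0.6 z per-cell subject spread. The
negative engagement-RT coupling dominates the positive load confound, so
the cell-level EI–RT correlation is negative (≈ −0.3 at cohort size).

Effect-size defaults are a modeling choice: no band-power effect sizes are
available to copy, so the theta gain was set so that an 11-subject study
detects the load effect with high power while a gain of 1 stays at the
nominal false-positive level, and the remaining gains were balanced to
produce the qualitative effect pattern the design targets (theta: load but
not modality; gamma: interaction only; EI: load effect, negative RT
coupling). Passing tests therefore validate the *pipeline's recovery of
known structure*, not any claim about real children; real EEG additionally
has correlated channels, non-stationary spectra, movement artifacts and
non-Poisson blink trains, none of which are modeled.

## Preprocessing

Filters: 50 Hz IIR notch (Q = 30) then 5th-order Butterworth band-pass
1–45 Hz, both applied forward–backward (`filtfilt`) so epoch-relative
timing is preserved; the effective magnitude response is squared, which is
accepted in exchange for zero phase. Filtering is idempotent in the
passband to within 2% RMS.

Blink removal substitutes a documented, identifiable procedure for the
original (undescribed) algorithm: blink windows are found on Fpz by a
matched filter (half-cosine template, threshold 3 robust SD of the response,
window = template ± 250 ms) with a 60 µV window-local amplitude gate so
background alone never opens a window; within each contiguous window,
every other channel is regressed on the centred Fpz signal and the fitted
component subtracted — per window, so a channel without blink content in
some window (e.g. a disconnected electrode) is untouched there. The
regression denominator subtracts the Fpz background variance estimated
outside windows (errors-in-variables correction); without it the
coefficient is attenuated by noise/signal and a systematic blink residue
survives. Non-blink segments are never modified; Fpz itself is kept for QC
and excluded from analysis clusters.

Epochs run from −500 ms to +3000 ms around onset (896 samples at 256 Hz);
events whose window leaves the recording are dropped with a logged warning.
Artifact criteria are evaluated per epoch on every analysis channel
(any-channel rule; whole epochs are removed): threshold ±80 µV; trend via
the ordinary least-squares slope over the full epoch, flagged above
40 µV/s; the "slope < 0.3 µV/s" branch is read as a flat/disconnected-
channel guard and paired with a < 1 µV peak-to-peak range check, since a
literal reading would reject nearly all clean epochs; jump = any successive-
sample difference above 30 µV (the stated "30 mV" is treated as a µV typo —
a 30 mV step cannot coexist with the ±80 µV criterion). All thresholds are
configurable; flagging is monotone in them.

## Spectral analysis

IAF: channel-averaged Welch spectrum (2 s Hanning windows, 50% overlap) of
the eyes-closed segment over posterior channels {O1, O2, Pz} (the feeding
channels are not prescribed; a posterior set is the convention for alpha),
searched in [7, 13] Hz with parabolic interpolation between bins. If the
in-range maximum sits at the range edge or is less than 1.5× the in-range
median PSD (no convincing peak, e.g. white noise), the canonical 10 Hz is
returned with a warning.

Band powers: Welch per epoch/channel, 1 s Hanning, 50% overlap, mean
detrending; band power integrates the PSD over [lo, hi) by rectangle rule,
so the four primary bands tile [IAF−6, IAF+30] without double counting.
Gamma's top is clipped to the 45 Hz analysis limit if it would exceed it.
Normalization to the baseline block is per channel and band *before*
cluster averaging (channel-specific baselines are respected; the order is
configurable), ratio by default with dB selectable; the transform is not
prescribed anywhere, and ratio keeps powers strictly positive. Legacy
channel names in cluster definitions (T3/T4/T5/T6) resolve through an alias
map to the recorded T7/T8/P7/P8. The parietal cluster defaults to
{P3, P4, P7, P8} (methods-text variant); a {Pz, P3, P7, P8} variant is
selectable. EI is computed per epoch from the raw (unnormalized)
cluster-averaged band powers over the 19 analysis channels, using the full
alpha band, then averaged within condition cells.

## Statistics

The factorial decomposition assumes subject as a random factor (every
subject contributes all six cells); sums of squares follow the balanced
two-way repeated-measures layout, each effect tested against its own
subject-by-effect interaction. A between-subject mode with a single pooled
residual is selectable for comparison. Normality is checked on cell
residuals (values minus cell means) — the tested quantity is not
prescribed, and residuals are what the F test assumes; on rejection at
α = 0.05 all values are rank-transformed (ranks over all observations) and
the identical decomposition is applied. Rank transform was chosen over
Friedman-type tests because it preserves the full factorial structure
including the interaction, and it is invariant to monotone transforms.

Duncan's multiple range test uses studentized-range quantiles at the
protection level α_r = 1 − (1−α)^(r−1) for a pair spanning r ordered means,
critical range q·√(MS_error/n), with the standard rule that no pair inside
a non-significant span is declared significant. Note that this protection
level makes the familywise null error rate grow with the number of groups
(≈ 0.0975 for three groups at α = 0.05) — a property of the procedure, not
a bug; the null-calibration suite therefore measures the two-group rate,
where the protection level equals the nominal α. Degenerate inputs
(constant tables, zero error SS) are reported as F = 0 / p = 1 rather than
NaN. The EI–RT correlation is computed across subject × condition cells
(n = 66 for 11 subjects), matching the design's reported degrees of
freedom.

## Problem sizes

The full pipeline simulates complete sessions (60 s eyes-closed + baseline
+ six task blocks ≈ 9 min of 20-channel EEG per subject-modality). The
replicate studies (statistical power, null calibration, coupling
sign-stability) instead simulate condition epochs directly — the same
generative model and the same spectral/stats code paths, without the
continuous-recording and filtering stages, which contribute nothing to
those questions — using 8 epochs per cell (theta study) and 6 per cell
(EI–RT study) over the channels the tested clusters need, 100 replicate
cohorts per suite. The acceptance script uses 50 replicates per study.

## Known limitations

* The simulator's independence across channels makes cluster averages less
  noisy than real data; detector false-positive rates on real EEG will be
  higher.
* Blink removal assumes a fixed spatial blink pattern per recording;
  slow ocular drift and saccades are not modeled or removed.
* The trend criterion is nearly inert after a 1 Hz zero-phase high-pass
  (epoch-long drifts are sub-threshold by construction); it matters mainly
  for flat/disconnected channels.
* Rank-transform ANOVA p-values are approximate for small samples; with
  n = 11 subjects this matches common practice but exact permutation tests
  are not provided.
* No topographic interpolation/plotting, time-frequency analysis or
  connectivity measures.
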