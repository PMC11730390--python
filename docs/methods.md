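# Methods notes

This note documents the models, defaults and design decisions behind
`nirspeech`, in the spirit of a methods appendix: what is simulated,
how the analysis chain is realized numerically, and what the passing
tests do and do not establish about real infant data.

## The paradigm and forward model

The simulated experiment is a block design: 10 blocks of forward and 10
of reverse speech, 15 s each, separated by silences drawn uniformly
from 15–30 s, pseudo-randomised with at most two consecutive blocks of
the same condition. The probe is a bilateral 24-channel montage (12 per
hemisphere) sampled at 10 Hz with continuous-wave light at 695 and
830 nm. The printed source–detector separation of 2 mm in the source
description is physiologically implausible for cortical fNIRS; the
default is 3.0 cm (typical neonatal probes). Distance only rescales
concentrations and cancels exactly in the laterality index.

Each subject's haemodynamic truth is parameterized by a designed
discrimination amplitude SP (µM), a designed laterality LI ∈ [−100,
100], and a response sign. The per-hemisphere forward−reverse
amplitude differences are d_L = SP·(1+LI/100) and d_R = SP·(1−LI/100);
the reverse-speech response is a common baseline amplitude (0.30 µM
HbO). HbR is modelled as −0.3 × HbO. Inverted responders (default
fraction 49/92 ≈ 0.53) have every concentration response sign-flipped,
so HbO decreases and HbR increases under stimulation.

The response kernel is a single gamma density with 7-s time-to-peak and
shape 8, no undershoot. The shape is chosen so that the response
returns to baseline within ~15 s of stimulus offset: the paradigm's
silences are sized for exactly that, and a heavier-tailed kernel would
leak the previous block's response into the next trial's baseline
window, which is a property of a kernel choice rather than of the
analysis under test. Downstream analysis uses only window means, so the
kernel's exact shape is otherwise immaterial. Block responses are
normalised so that one isolated block's mean over the 0–25 s analysis
window equals the designed amplitude; designed SP values are therefore
on the same scale as measured SP values.

Group truth distributions default to the study-cohort amplitudes:
SP ~ truncated normal with mean 0.14 (sd 0.11) for term and 0.10 (sd
0.08) for preterm subjects, floored at 0.005 µM (a subject with exactly
zero amplitude has no defined laterality). The truncation location is
calibrated numerically so the realized group means equal the design
means; the realized sds compress somewhat (≈0.06/0.09) — the group
means and their difference are the emulation target. Designed LI is a
truncated normal, mean 0, sd 47.3, bounded at ±100.

## Noise and artifact model

Concentration-domain noise per channel (HbO scale, µM; HbR gets the
same components × 0.3 with independent phases):

| component | default | rationale |
|---|---|---|
| white noise | 0.30 /sample | single-trial SNR < 1, as in real fNIRS; block averaging is what makes the response visible |
| Mayer wave, 0.1 Hz | 0.15 | in-band blood-pressure oscillation; the irreducible noise floor of this design |
| respiratory, 0.7 Hz | 0.10 | removed by the band-pass |
| cardiac, 2.5 Hz | 0.20 | neonatal heart rate ≈ 150/min; removed by the band-pass |
| slow drift | 0.30 (rms) | white noise low-passed below 0.01 Hz; below the high-pass edge |

The oscillatory components carry a random-walk phase (default jitter
0.02–0.05 rad/sample): physiological rhythms are not phase-locked over
minutes, and perfectly coherent sinusoids would bias trial averages in
a way real rhythms do not.

Motion artifacts are injected in the optical-density domain, where they
physically arise (coupling changes): brief Gaussian spikes (0.55–0.9
OD, 0.2–0.6 s FWHM, ≈0.3/min, all channels with gain 0.8–1.2) and
persistent baseline steps (0.6–1.2 OD, ≈0.05/min, each hitting a random
~15% subset of channels, as when one probe pad slips). Amplitudes are
large relative to haemodynamics — a 0.6 OD step is a ~40 µM-equivalent
excursion — because real coupling artifacts are; this puts them firmly
above the detection thresholds and exercises both correction paths and
the channel-pruning bookkeeping (a step in mid-recording typically
drives that channel's SNR below 2, which is how such channels are lost
in practice).

## The preprocessing chain

Order is fixed: OD → SNR pruning → motion detection → spline →
wavelet → band-pass → Beer–Lambert → epoching.

* **OD conversion** uses the full-recording mean as reference. The
  resulting per-channel constant offset is irrelevant: every epoch is
  baseline-corrected.
* **SNR pruning**: mean/sd of raw intensity ≥ 2 at both wavelengths.
  Zero-variance channels count as infinite SNR (retained, logged).
* **Motion detection** flags samples where the excursion (max−min)
  within a 0.5-s sliding window exceeds min(50 × scale, 0.4 OD), where
  the scale is a MAD-based robust std of the first differences — robust
  so that artifacts cannot inflate the scale and mask themselves. Flags
  are dilated by 1 s per side; wavelengths are OR-combined per channel.
* **Spline correction** fits a cubic smoothing spline (csaps-style
  p = 0.99, λ = (1−p)/p on a sample axis) inside each flagged run,
  subtracts it, and re-anchors the residual at the pre-run level A.
  When the level difference |A − B| across the run (A, B: means of
  unflagged samples in 30-s flanking windows) exceeds 0.2 OD — half the
  absolute detection threshold, separating true steps (≥ 0.4 OD) from
  haemodynamic level noise (~0.003 OD) by two orders of magnitude — all
  subsequent samples are shifted by A − B. Steps are thereby removed;
  an isolated spike leaves everything outside its run untouched. Runs
  shorter than 3 samples are mean-subtracted.
* **Wavelet despiking** (Daubechies-2, symmetric padding, maximum
  depth) zeroes detail coefficients outside [Q1 − 0.5·IQR, Q3 +
  0.5·IQR] per level. Detail levels with centre pseudo-frequency below
  0.1 Hz are not thresholded: the step targets brief artifacts, which
  live at fine scales, while the coarse scales carry the slow
  haemodynamic response — on those levels the quartiles are
  signal-dominated and thresholding would excise the response itself.
* **Band-pass**: 3rd-order Butterworth, 0.01–0.50 Hz, applied forward
  and backward (zero phase).
* **Epoching**: per block, [−2, 25) s at 10 Hz (270 samples,
  half-open), baseline = mean of the continuous series over [−5, 0) s.
  A trial is rejected when the mean fraction of flagged samples across
  retained channels in its window exceeds 10%. Subjects are included
  iff ≥ 18 channels and ≥ 50% of trials survive (boundaries count as
  included).

## Metrics

Aggregation order: per-channel forward−reverse window means (0–25 s)
are averaged across channels first, then the absolute value is taken
(the "difference in mean changes within all channels" reading); the
per-channel-absolute-first variant is available behind `abs_first` for
sensitivity analysis. Channels discarded for a subject are simply
dropped from that subject's means, not imputed. Sign classification:
inverted iff the all-channel forward-condition window mean of ΔHbO is
negative; an exact zero classifies as positive and is logged as
ambiguous. LI is undefined (and the subject excluded from laterality
analyses) when SP_L + SP_R = 0.

## Outcome model

Phonological short-term-memory z-scores follow z = mean + slope·(LI/100)
+ ε with slope 1.35; the residual sd (≈0.95) is derived from the target
rank correlation 0.5 via Greiner's relation ρ = 2·sin(πρ_s/6) and the
sd of the truncated-normal LI marginal. With the bounded LI marginal
the large-n empirical Spearman is ≈0.51, within 0.02 of target.
Sentence production and morphological rules share a rank correlation of
0.52 (Gaussian copula); comprehension is independent. Group membership
does not shift outcome means — group effects enter only through the
amplitude distributions — mirroring a cohort in which language outcomes
did not differ significantly by group. Marginal means/sds follow the
cohort table descriptives.

## Statistics

The mixed 2×2×2 ANOVA is computed from subject-level contrast
variables (subject mean; condition, hemisphere and interaction
contrasts), which for 2-level factors is algebraically the Type-III
mixed-design partition: each within effect is tested against its
effect-by-subject error with df (1, N−2), main effects use unweighted
group means, and partial η² = F/(F + df_err). Tests verify equality
with a loop-based sums-of-squares partition and with contrast
t-squares. Both one- and two-tailed p-values are emitted for the group
t-tests, with the report labelling each, since tail conventions differ
between reports. KS normality uses the Lilliefors correction
(parameters estimated from the sample). Mann–Whitney U uses exact
enumeration for min(n) ≤ 8 without ties, else the tie-corrected normal
approximation (z reported without continuity correction). Spearman
uses exact permutation below n = 10. The Bonferroni family for the
metric × outcome grid defaults to all 16 cells. Missing metrics
(undefined LI) are handled by pairwise deletion with per-cell n
reported.

## Problem sizes

The shipped study drivers simulate the full 92-subject cohort. The
test suite uses a 40-subject recovery experiment for laterality
(designed LI spanning [−80, 80] at the term-group mean amplitude,
default noise) and 500 truth-level replicate cohorts of n = 45 for the
outcome-coupling recovery and the null-coupling false-positive control;
truth-level cohorts skip the optical forward model because the quantity
under test there is the outcome coupling and the statistics stage,
while the optical chain is covered by the round-trip and recovery
tests.

## What passing tests do and do not show

The generator reproduces the statistical structure the analysis
assumes — block timing, response scale, inverted responders, in-band
and out-of-band noise, two artifact classes, designed group differences
and outcome couplings — but not everything about real infant data: no
scalp/optode geometry or photon transport, no superficial/systemic
component shared across channels, no state changes (sleep stage,
arousal) modulating responses over the session, artifact waveforms are
stylized, and channel noise is independent across channels apart from
the global artifact events. Passing the recovery tests therefore shows
the chain is correct and self-consistent under realistic amplitudes
and noise, not that the specific thresholds are optimal for any given
instrument.

## Known limitations

* The wavelet and band-pass stages attenuate measured SP by roughly
  10–25% depending on the schedule; LI is unaffected (common scaling
  cancels), and group comparisons are scale-invariant.
* Spearman's exact permutation p is O(n!) and is cut off at n = 10.
* The SNIRF writer covers the continuous-wave subset of the format
  plus a small custom group for hemisphere labels; it is not a general
  SNIRF round-trip tool.
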