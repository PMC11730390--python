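# nirspeech

Neonatal fNIRS speech-discrimination analysis: a tested, reusable
implementation of the pipeline that takes raw two-wavelength optical
intensities from a block-design forward/reverse-speech paradigm to
per-subject discrimination and laterality metrics, and on to the cohort
statistics linking neonatal lateralization to later language outcomes.
A seeded synthetic-cohort generator with known ground truth stands in
for infant recordings, so every stage is testable end to end without
any data download.

## Who this is for

Researchers working with infant functional near-infrared spectroscopy
(fNIRS) who want a transparent, scriptable version of the standard
block-design analysis chain — and a forward model to validate it
against known truth.

## The analysis

**Preprocessing** (fixed order): raw intensity → optical density
`ΔOD = −log10(I/Ī)` → SNR channel pruning (mean/sd ≥ 2 at both
wavelengths) → motion detection (sliding-window excursion vs. robust
scale and absolute thresholds) → spline correction of flagged segments
with step re-leveling → wavelet despiking (IQR rule, α = 0.5, scales
below 0.1 Hz protected) → zero-phase 0.01–0.50 Hz Butterworth band-pass
→ modified Beer–Lambert inversion → block averages over [−2, 25) s with
a [−5, 0) s baseline. The Beer–Lambert step solves, per channel and
sample,

    ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR] · d · DPF(λ)

with the differential pathlength factor from the general wavelength/age
equation (neonate: DPF(695 nm) = 5.31, DPF(830 nm) = 4.67).

**Metrics.** Speech discrimination SP is the absolute difference of the
mean haemodynamic (ΔHbO) response between forward and reverse speech
over all retained channels; SP_L and SP_R restrict to one hemisphere.
The laterality index

    LI_SP = (SP_L − SP_R) / (SP_L + SP_R) · 100

spans −100 (complete right dominance) to +100 (complete left
dominance). Because roughly half of neonates show inverted HbO
responses, absolute values are used by default and signed (algebraic)
variants are emitted for sign-split analyses.

**Statistics.** Lilliefors-corrected KS normality screening; a mixed
2×2×2 repeated-measures ANOVA (condition × hemisphere within, group
between) with partial η²; paired/two-sample t-tests; Mann–Whitney U;
Pearson and Spearman correlations (exact permutation p at small n);
Bonferroni families (p < 0.05/16 for the 4×4 metric × outcome grid);
slope-homogeneity F-tests; the socioeconomic composite; z-score band
classification.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
simulated cohort of 46 preterm and 46 term neonates (recordings land in
`scratch/`, tables in `results/`):

```bash
python analysis/01_simulate_cohort.py --seed 42
python analysis/02_preprocess.py
python analysis/03_metrics.py
python analysis/04_cohort_stats.py
```

With seed 42 this prints, among other things:

```
preprocessed 92 subjects; excluded 5
mean retained channels: 22.60

             variable  test  preterm_mean  term_mean  statistic  p_two_sided
                   sp     t        0.0823     0.1321     3.8294       0.0002
                li_sp     t        4.6372     2.6747    -0.1948       0.8460

 li_sp    z_phonological_stm  r_s 0.5122  p 0.0000   bonferroni_significant
```

Reading this: five simulated subjects fail the inclusion rule (at least
18 retained channels and at least half the trials); preterm subjects
show smaller discrimination amplitudes than term subjects (designed
into the generator as 0.10 vs 0.14 µM) while the laterality index does
not differ by group; and the laterality index correlates with the
phonological short-term-memory z-score at r_s ≈ 0.51, surviving the
Bonferroni family of 16 — recovering the generator's designed coupling
(rank correlation 0.5).

The same chain is available as a CLI (`nirspeech simulate | preprocess
| metrics | stats | run-all`) and as library functions
(`nirspeech.simulate_cohort`, `nirspeech.preprocess_subject`,
`nirspeech.compute_subject_metrics`, `nirspeech.mixed_anova_2x2x2`, …).

## Layout

```
src/nirspeech/     library: probe, schedule, hrf, optics, simulate,
                   preprocess, metrics, stats, io, pipeline, cli
analysis/          numbered study drivers (simulate → stats)
tests/             pytest suite incl. end-to-end acceptance checks
scripts/           acceptance.py
docs/methods.md    model and design notes
```
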