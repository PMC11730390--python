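"""Synthetic neonatal fNIRS cohorts with known ground truth.

The generator inverts the analysis chain: designed per-hemisphere
condition differences are convolved with a canonical response kernel,
physiological noise and motion artifacts are added, and the
concentration signal is mapped to raw two-wavelength intensities
through the same modified Beer-Lambert model the preprocessing stage
inverts.  Defaults emulate the study conditions: 24-channel bilateral
probe at 10 Hz, 10 blocks of 15 s per condition with 15-30 s silences,
group discrimination amplitudes of 0.14 (term) vs 0.10 µM (preterm),
roughly half the subjects with inverted HbO responses, and language
outcomes in which phonological short-term memory couples to left
lateralization at a design rank correlation of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hrf import block_response, gamma_kernel
from .optics import EXTINCTION_1_PER_MM_CM, conc_to_od
from .preprocess import RawRecording
from .probe import ProbeLayout, default_layout
from .schedule import CONDITIONS, StimulusSchedule, make_schedule
from .stats import ses_composite

HEMISPHERES = ("L", "R")


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# truth and noise models
# ---------------------------------------------------------------------------

@dataclass
class NoiseConfig:
    """Amplitudes of the additive noise components (HbO scale, µM).

    HbR receives the same components scaled by ``hbr_scale`` with
    independent phases.  Motion artifacts are injected in the OD domain:
    ``spike``s are brief Gaussian bumps (0.2-1 s), ``shift``s are
    persistent baseline steps; both occur as Poisson processes at the
    given rates and affect all channels with random per-channel gains.
    """

    white_sd: float = 0.30
    mayer_amp: float = 0.15     # ~0.1 Hz blood-pressure wave, in band
    mayer_freq_hz: float = 0.1
    mayer_phase_jitter: float = 0.02   # rad/sample phase diffusion
    resp_amp: float = 0.10      # respiratory component
    resp_freq_hz: float = 0.7
    resp_phase_jitter: float = 0.05
    cardiac_amp: float = 0.20   # neonatal heart rate ~150/min
    cardiac_freq_hz: float = 2.5
    cardiac_phase_jitter: float = 0.05
    drift_sd: float = 0.30      # broadband very-low-frequency drift (µM)
    drift_cutoff_hz: float = 0.01
    hbr_scale: float = 0.3
    spike_rate_per_min: float = 0.3
    spike_amp_od: tuple = (0.55, 0.9)
    spike_width_s: tuple = (0.2, 0.6)
    shift_rate_per_min: float = 0.05
    shift_amp_od: tuple = (0.6, 1.2)
    shift_channel_prob: float = 0.15   # fraction of channels hit per event

    @classmethod
    def none(cls) -> "NoiseConfig":
        """Noise-free configuration (round-trip testing)."""
        return cls(white_sd=0.0, mayer_amp=0.0, resp_amp=0.0, cardiac_amp=0.0,
                   drift_sd=0.0, spike_rate_per_min=0.0, shift_rate_per_min=0.0)


@dataclass
class SubjectTruth:
    """Designed ground truth for one simulated subject.

    ``amp`` maps (condition, hemisphere) to the designed peak ΔHbO
    response in µM (already sign-flipped for inverted responders).
    Designed metrics are on the per-channel condition-difference scale:
    true_sp = (|d_L| + |d_R|)/2 with d_h the forward-reverse amplitude
    difference in hemisphere h.
    """

    subject_id: str
    group: str                      # "preterm" | "term"
    sign: str                       # "pos" | "inv"
    amp: dict
    true_sp: float
    true_sp_l: float
    true_sp_r: float
    true_li: float
    seed: int

    def __post_init__(self):
        if self.group not in ("preterm", "term"):
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.sign not in ("pos", "inv"):
            raise ConfigurationError(f"unknown sign {self.sign!r}")
        if not -100.0 <= self.true_li <= 100.0:
            raise ConfigurationError("designed LI outside [-100, 100]")


@dataclass
class GroupTruthConfig:
    """Distribution of designed discrimination amplitudes for one group."""

    sp_mean: float
    sp_sd: float
    li_mean: float = 0.0
    li_sd: float = 47.3
    inv_fraction: float = 49.0 / 92.0
    reverse_amp: float = 0.30   # baseline response to reverse speech, µM
    sp_floor: float = 0.005     # lowest designed amplitude, keeps LI defined

    def __post_init__(self):
        if self.sp_sd < 0 or self.li_sd < 0:
            raise ConfigurationError("distribution sd must be non-negative")
        if not 0 <= self.inv_fraction <= 1:
            raise ConfigurationError("inv_fraction must be in [0, 1]")


#: Study-condition defaults: Table-2-style group amplitude distributions.
DEFAULT_TRUTH = {
    "term": GroupTruthConfig(sp_mean=0.14, sp_sd=0.11),
    "preterm": GroupTruthConfig(sp_mean=0.10, sp_sd=0.08),
}


def _trunc_normal(mean, sd, lo, hi, rng, size=None, calibrate=False):
    """Truncated-normal draw; with ``calibrate`` the location is solved
    so the truncated mean equals ``mean`` (one-sided truncation shifts
    the mean upward otherwise)."""
    if sd == 0:
        return np.clip(np.full(size, mean) if size else float(mean), lo, hi)
    loc = mean
    if calibrate:
        from scipy.optimize import brentq

        def gap(m):
            a, b = (lo - m) / sd, (hi - m) / sd
            return sps.truncnorm.mean(a, b, loc=m, scale=sd) - mean

        span = 6 * sd + abs(mean)
        loc = brentq(gap, mean - span, mean + span, xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return sps.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def designed_truth(subject_id: str, sp: float, li: float, sign: str = "pos",
                   group: str = "term", reverse_amp: float = 0.30,
                   seed: int = 0) -> SubjectTruth:
    """Construct a subject with exactly the given designed SP and LI.

    The per-hemisphere forward-reverse differences are
    d_L = sp*(1 + li/100), d_R = sp*(1 - li/100); inverted responders
    get all amplitudes sign-flipped (HbR flips oppositely in the
    forward model).
    """
    d_l = sp * (1.0 + li / 100.0)
    d_r = sp * (1.0 - li / 100.0)
    flip = -1.0 if sign == "inv" else 1.0
    amp = {("reverse", h): flip * reverse_amp for h in HEMISPHERES}
    amp[("forward", "L")] = flip * (reverse_amp + d_l)
    amp[("forward", "R")] = flip * (reverse_amp + d_r)
    return SubjectTruth(subject_id=subject_id, group=group, sign=sign, amp=amp,
                        true_sp=sp, true_sp_l=abs(d_l), true_sp_r=abs(d_r),
                        true_li=li, seed=seed)


def draw_truth(subject_id: str, group: str, cfg: GroupTruthConfig,
               rng: np.random.Generator, seed: int = 0) -> SubjectTruth:
    """Sample one subject's designed amplitudes, laterality and sign."""
    sp = float(_trunc_normal(cfg.sp_mean, cfg.sp_sd, cfg.sp_floor, np.inf, rng,
                             calibrate=True))
    li = float(_trunc_normal(cfg.li_mean, cfg.li_sd, -100.0, 100.0, rng))
    sign = "inv" if rng.random() < cfg.inv_fraction else "pos"
    return designed_truth(subject_id, sp, li, sign=sign, group=group,
                          reverse_amp=cfg.reverse_amp, seed=seed)


# ---------------------------------------------------------------------------
# forward signal model
# ---------------------------------------------------------------------------

def designed_response(truth: SubjectTruth, layout: ProbeLayout,
                      sched: StimulusSchedule, fs: float, n_samples: int,
                      hrf_peak_s: float = 7.0):
    """Noise-free designed ΔHbO/ΔHbR (µM), shape (C, T) each."""
    kernel = gamma_kernel(fs, peak_s=hrf_peak_s)
    dhbo = np.zeros((layout.n_channels, n_samples))
    for cond in CONDITIONS:
        onsets = [o for o, _, c in sched.blocks() if c == cond]
        if not onsets:
            continue
        resp = block_response(n_samples, fs, onsets, float(sched.duration_s[0]),
                              kernel)
        for h in HEMISPHERES:
            idx = layout.channels_in(h)
            dhbo[idx] += truth.amp[(cond, h)] * resp
    dhbr = -0.3 * dhbo
    return dhbo, dhbr


def _physio_noise(shape, fs, cfg: NoiseConfig, rng) -> np.ndarray:
    """White noise, quasi-periodic oscillations and broadband drift.

    Oscillations carry a slow random-walk phase (physiological rhythms
    are not phase-locked over minutes); drift is white noise low-passed
    below ``drift_cutoff_hz`` and rescaled to ``drift_sd``.
    """
    from scipy import signal as ssig
    c, t = shape
    tt = np.arange(t) / fs
    out = rng.normal(0.0, cfg.white_sd, size=shape) if cfg.white_sd else np.zeros(shape)
    for amp, freq, jitter in ((cfg.mayer_amp, cfg.mayer_freq_hz, cfg.mayer_phase_jitter),
                              (cfg.resp_amp, cfg.resp_freq_hz, cfg.resp_phase_jitter),
                              (cfg.cardiac_amp, cfg.cardiac_freq_hz, cfg.cardiac_phase_jitter)):
        if amp:
            phase0 = rng.uniform(0, 2 * np.pi, size=(c, 1))
            walk = np.cumsum(rng.normal(0.0, jitter, size=shape), axis=-1)
            out += amp * np.sin(2 * np.pi * freq * tt[None, :] + phase0 + walk)
    if cfg.drift_sd:
        sos = ssig.butter(2, cfg.drift_cutoff_hz, btype="lowpass", fs=fs,
                          output="sos")
        raw = rng.normal(size=shape)
        slow = ssig.sosfiltfilt(sos, raw, axis=-1)
        sd = slow.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        out += cfg.drift_sd * slow / sd
    return out


def _motion_artifacts(shape, fs, cfg: NoiseConfig, rng) -> np.ndarray:
    """OD-domain artifacts shared in time across channels."""
    c, w, t = shape
    out = np.zeros(shape)
    minutes = t / fs / 60.0
    tt = np.arange(t) / fs
    n_spikes = rng.poisson(cfg.spike_rate_per_min * minutes)
    for _ in range(n_spikes):
        t0 = rng.uniform(0, t / fs)
        width = rng.uniform(*cfg.spike_width_s)
        amp = rng.uniform(*cfg.spike_amp_od) * rng.choice([-1.0, 1.0])
        gain = rng.uniform(0.8, 1.2, size=(c, w, 1))
        bump = np.exp(-0.5 * ((tt - t0) / (width / 2.355)) ** 2)  # FWHM=width
        out += amp * gain * bump[None, None, :]
    n_shifts = rng.poisson(cfg.shift_rate_per_min * minutes)
    for _ in range(n_shifts):
        i0 = int(rng.uniform(0, t))
        amp = rng.uniform(*cfg.shift_amp_od) * rng.choice([-1.0, 1.0])
        hit = rng.random(c) < cfg.shift_channel_prob  # probe-pad slip: subset
        gain = rng.uniform(0.8, 1.2, size=(c, w, 1)) * hit[:, None, None]
        step = np.zeros(t)
        step[i0:] = 1.0
        out += amp * gain * step[None, None, :]
    return out


def simulate_subject(truth: SubjectTruth, layout: ProbeLayout | None = None,
                     sched: StimulusSchedule | None = None,
                     noise: NoiseConfig | None = None, fs: float = 10.0,
                     i0: float = 1.0, pad_s: float = 35.0,
                     hrf_peak_s: float = 7.0,
                     extinction: dict | None = None,
                     age_years: float = 0.0,
                     rng: np.random.Generator | None = None) -> RawRecording:
    """Forward-simulate one subject's raw two-wavelength intensities."""
    if i0 <= 0:
        raise ConfigurationError("reference intensity I0 must be positive")
    layout = layout or default_layout()
    sched = sched if sched is not None else make_schedule(10, seed=truth.seed)
    noise = noise or NoiseConfig()
    rng = rng or np.random.default_rng(truth.seed)
    n = int(round((sched.end_s() + pad_s) * fs))
    dhbo, dhbr = designed_response(truth, layout, sched, fs, n, hrf_peak_s)
    dhbo = dhbo + _physio_noise(dhbo.shape, fs, noise, rng)
    dhbr = dhbr + noise.hbr_scale * _physio_noise(dhbr.shape, fs, noise, rng)
    ext = EXTINCTION_1_PER_MM_CM if extinction is None else extinction
    dod = conc_to_od(dhbo, dhbr, layout, ext, age_years)
    dod = dod + _motion_artifacts(dod.shape, fs, noise, rng)
    intensity = i0 * np.power(10.0, -dod)
    return RawRecording(intensity=intensity, fs=fs, layout=layout,
                        subject_id=truth.subject_id)


# ---------------------------------------------------------------------------
# outcome model
# ---------------------------------------------------------------------------

@dataclass
class OutcomeModel:
    """Generative model of the four language-outcome z-scores.

    Phonological short-term memory follows
    ``z = mean + slope*(LI/100) + eps``; the residual sd is derived (when
    not given) from the target rank correlation via Greiner's relation
    rho = 2*sin(pi*rho_s/6) and the sd of the designed LI distribution.
    Sentence production and morphological rules share a rank correlation;
    comprehension is independent.
    """

    stm_slope: float = 1.35
    stm_noise_sd: float | None = None
    target_rank_corr: float = 0.50
    li_sd: float = 47.3
    stm_mean: float = -0.05
    comprehension_mean: float = 0.38
    comprehension_sd: float = 1.07
    sentence_mean: float = 0.11
    sentence_sd: float = 1.05
    morphology_mean: float = -0.10
    morphology_sd: float = 1.24
    morph_sentence_rank_corr: float = 0.52

    def residual_sd(self) -> float:
        if self.stm_noise_sd is not None:
            return self.stm_noise_sd
        if self.stm_slope == 0 or self.target_rank_corr == 0:
            return 1.0
        rho = 2.0 * np.sin(np.pi * self.target_rank_corr / 6.0)
        a, b = -100.0 / self.li_sd, 100.0 / self.li_sd
        sig_l = self.li_sd * sps.truncnorm.std(a, b) / 100.0
        return abs(self.stm_slope) * sig_l * np.sqrt(1.0 / rho ** 2 - 1.0)


def generate_outcomes(true_li: np.ndarray, model: OutcomeModel | None = None,
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw the four outcome z-scores given designed laterality indices."""
    model = model or OutcomeModel()
    li = np.asarray(true_li, dtype=float)
    if np.any((li < -100) | (li > 100)):
        raise ConfigurationError("LI values must lie in [-100, 100]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(li)
    stm = model.stm_mean + model.stm_slope * (li / 100.0) + \
        rng.normal(0.0, model.residual_sd(), size=n)
    rho = 2.0 * np.sin(np.pi * model.morph_sentence_rank_corr / 6.0)
    z1 = rng.normal(size=n)
    z2 = rho * z1 + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
    sentence = model.sentence_mean + model.sentence_sd * z1
    morph = model.morphology_mean + model.morphology_sd * z2
    comp = rng.normal(model.comprehension_mean, model.comprehension_sd, size=n)
    return pd.DataFrame({
        "z_comprehension": comp,
        "z_sentence_production": sentence,
        "z_morphological_rules": morph,
        "z_phonological_stm": stm,
    })


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    truth: SubjectTruth
    schedule: StimulusSchedule
    recording: RawRecording | None


def simulate_cohort(n_preterm: int = 46, n_term: int = 46,
                    truth: dict | None = None,
                    outcome_model: OutcomeModel | None = None,
                    noise: NoiseConfig | None = None,
                    seed: int = 0, raw: bool = True,
                    layout: ProbeLayout | None = None,
                    n_per_condition: int = 10,
                    block_dur: float = 15.0,
                    isi_range: tuple = (15.0, 30.0),
                    fs: float = 10.0):
    """Simulate a labelled cohort.

    Returns ``(subjects, cohort)`` where ``subjects`` is a list of
    :class:`SubjectRecord` and ``cohort`` a per-subject DataFrame of
    group, covariates, designed metrics and outcome z-scores.  With
    ``raw=False`` the optical recordings are skipped (truth-level
    cohort) — used for statistics-stage Monte-Carlo work.
    """
    if n_preterm + n_term < 2:
        raise ConfigurationError("need at least 2 subjects")
    truth_cfg = {**DEFAULT_TRUTH, **(truth or {})}
    layout = layout or default_layout()
    ss = np.random.SeedSequence(seed)
    groups = ["preterm"] * n_preterm + ["term"] * n_term
    child_seeds = ss.spawn(len(groups) + 1)
    rng_cohort = np.random.default_rng(child_seeds[-1])

    subjects, rows = [], []
    for i, group in enumerate(groups):
        sub_seed = int(child_seeds[i].generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(child_seeds[i])
        sid = f"{'P' if group == 'preterm' else 'T'}{i + 1:03d}"
        tr = draw_truth(sid, group, truth_cfg[group], rng, seed=sub_seed)
        sched = make_schedule(n_per_condition, block_dur, isi_range,
                              max_run=2, seed=rng)
        rec = simulate_subject(tr, layout, sched, noise, fs=fs, rng=rng) \
            if raw else None
        subjects.append(SubjectRecord(truth=tr, schedule=sched, recording=rec))
        if group == "preterm":
            ga = rng_cohort.uniform(25.0, 36.9)
        else:
            ga = rng_cohort.uniform(37.0, 41.9)
        ses = ses_composite(int(rng_cohort.integers(1, 6)),
                            int(rng_cohort.integers(1, 6)),
                            int(rng_cohort.integers(1, 9)))
        rows.append({"subject_id": sid, "group": group,
                     "sex": "f" if rng_cohort.random() < 0.5 else "m",
                     "gestational_age_wk": round(ga, 1), "ses": ses,
                     "sign": tr.sign, "true_sp": tr.true_sp,
                     "true_sp_l": tr.true_sp_l, "true_sp_r": tr.true_sp_r,
                     "true_li": tr.true_li})
    cohort = pd.DataFrame(rows)
    out_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
    outcomes = generate_outcomes(cohort["true_li"].to_numpy(), outcome_model,
                                 seed=out_seed)
    cohort = pd.concat([cohort, outcomes], axis=1)
    return subjects, cohort
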