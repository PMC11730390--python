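"""Signal chain from raw two-wavelength intensities to block averages.

The chain order is fixed: optical density -> SNR channel pruning ->
motion detection -> spline correction -> wavelet correction ->
band-pass -> modified Beer-Lambert -> epoching/averaging.  Every
discarded channel and trial is accounted for in the returned logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage, signal
from scipy.interpolate import make_smoothing_spline

from .optics import EXTINCTION_1_PER_MM_CM, od_to_conc
from .probe import ProbeLayout
from .schedule import StimulusSchedule

logger = logging.getLogger(__name__)


class DataError(ValueError):
    """Malformed or physically impossible input data."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """Per-channel, per-wavelength optical intensities.

    intensity has shape (n_channels, n_wavelengths, n_samples), arbitrary
    units, strictly positive.
    """

    intensity: np.ndarray
    fs: float
    layout: ProbeLayout
    subject_id: str = "subject"

    def __post_init__(self):
        c, w, _ = self.intensity.shape
        if c != self.layout.n_channels or w != self.layout.n_wavelengths:
            raise DataError("intensity shape does not match probe layout")
        if not np.all(np.isfinite(self.intensity)):
            raise DataError("non-finite intensities")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[-1]


@dataclass
class ODSeries:
    """Optical-density changes, shape (n_channels, n_wavelengths, n_samples)."""

    dod: np.ndarray
    fs: float
    layout: ProbeLayout


@dataclass
class ConcSeries:
    """Concentration changes in µM, shape (n_channels, n_samples) each."""

    dhbo: np.ndarray
    dhbr: np.ndarray
    fs: float
    layout: ProbeLayout


@dataclass
class EpochAverage:
    """Per-condition block averages over the epoch window.

    dhbo/dhbr map condition -> array (n_retained_channels, n_window_samples);
    a condition with zero retained trials maps to None.
    """

    time_s: np.ndarray
    dhbo: dict
    dhbr: dict
    n_trials: dict
    channel_index: np.ndarray  # positional indices into layout of retained channels
    layout: ProbeLayout
    fs: float


@dataclass
class InclusionDecision:
    retained_channels: int
    retained_trial_fraction: float
    included: bool
    reasons: list = field(default_factory=list)


@dataclass
class PreprocessConfig:
    """All tunables of the preprocessing chain (defaults as documented)."""

    snr_thresh: float = 2.0
    t_motion_s: float = 0.5
    t_mask_s: float = 1.0
    std_thresh: float = 50.0
    amp_thresh: float = 0.4
    spline_p: float = 0.99
    wavelet_alpha: float | None = 0.5
    wavelet: str = "db2"
    f_lo_hz: float = 0.01
    f_hi_hz: float = 0.50
    filter_order: int = 3
    window_s: tuple = (-2.0, 25.0)
    baseline_s: tuple = (-5.0, 0.0)
    trial_reject_tol: float = 0.10
    min_channels: int = 18
    min_trial_fraction: float = 0.5
    age_years: float = 0.0
    extinction: dict = field(default_factory=lambda: dict(EXTINCTION_1_PER_MM_CM))
    do_motion: bool = True
    do_spline: bool = True
    do_wavelet: bool = True
    do_bandpass: bool = True


# ---------------------------------------------------------------------------
# chain steps
# ---------------------------------------------------------------------------

def intensity_to_od(rec: RawRecording) -> ODSeries:
    """Convert intensities to optical-density changes.

    dOD = -log10(I / mean(I)) per channel and wavelength, the mean taken
    over the full recording.
    """
    if np.any(rec.intensity <= 0):
        bad = np.argwhere(np.any(rec.intensity <= 0, axis=-1))
        ch = rec.layout.channel_id[bad[0][0]]
        raise DataError(f"non-positive intensity in channel {ch}")
    ref = rec.intensity.mean(axis=-1, keepdims=True)
    dod = -np.log10(rec.intensity / ref)
    return ODSeries(dod=dod, fs=rec.fs, layout=rec.layout)


def channel_snr(rec: RawRecording) -> np.ndarray:
    """Signal-to-noise ratio mean/sd of raw intensity, shape (C, W).

    Zero-variance channels get infinite SNR (retained, logged)."""
    mean = rec.intensity.mean(axis=-1)
    sd = rec.intensity.std(axis=-1, ddof=0)
    with np.errstate(divide="ignore"):
        snr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf)
    if np.any(sd == 0):
        logger.info("zero-variance channel(s) treated as infinite SNR: %s",
                    rec.layout.channel_id[np.any(sd == 0, axis=-1)].tolist())
    return snr


def prune_channels(rec: RawRecording, snr_thresh: float = 2.0) -> np.ndarray:
    """Boolean keep-mask: channel retained iff SNR >= threshold at every
    wavelength."""
    if rec.n_samples <= 1:
        raise DataError("recording too short for SNR estimation")
    snr = channel_snr(rec)
    return np.all(snr >= snr_thresh, axis=-1)


def detect_motion(od: ODSeries, t_motion_s: float = 0.5, t_mask_s: float = 1.0,
                  std_thresh: float = 50.0, amp_thresh: float = 0.4) -> np.ndarray:
    """Flag motion-contaminated samples per channel.

    A sample is flagged when the signal excursion (max - min) within any
    sliding window of length ``t_motion_s`` containing it exceeds
    ``std_thresh`` times the channel's sample-to-sample change scale
    (a robust MAD-based std of the first differences, so artifacts
    cannot mask themselves) or ``amp_thresh`` in absolute OD.
    Flags are then dilated by ``t_mask_s`` on each side.  Wavelengths
    are combined with OR.  Zero-variance traces contribute through the
    absolute criterion only.
    """
    for name, v in (("t_motion_s", t_motion_s), ("t_mask_s", t_mask_s),
                    ("std_thresh", std_thresh), ("amp_thresh", amp_thresh)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    c, w, t = od.dod.shape
    win = max(2, int(round(t_motion_s * od.fs)))
    flags = np.zeros((c, t), dtype=bool)
    for ci in range(c):
        for wi in range(w):
            y = od.dod[ci, wi]
            mx = ndimage.maximum_filter1d(y, size=win, mode="nearest")
            mn = ndimage.minimum_filter1d(y, size=win, mode="nearest")
            exc = mx - mn
            dy = np.diff(y)
            sd = 1.4826 * np.median(np.abs(dy - np.median(dy))) \
                if len(dy) else 0.0
            thresh = amp_thresh if sd == 0 else min(std_thresh * sd, amp_thresh)
            flags[ci] |= exc > thresh
    pad = int(round(t_mask_s * od.fs))
    if pad > 0:
        flags = ndimage.maximum_filter1d(flags, size=2 * pad + 1, axis=-1,
                                         mode="constant")
    return flags


def _runs(mask_1d: np.ndarray):
    """Contiguous True runs as (start, stop) index pairs, stop exclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask_1d.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def spline_correct(od: ODSeries, mask: np.ndarray, p: float = 0.99,
                   level_window_s: float = 30.0,
                   relevel_thresh_od: float = 0.2) -> ODSeries:
    """Subtract a cubic smoothing-spline fit within each flagged segment
    and re-level so segment means are continuous across boundaries.

    Within a flagged run the smoothing spline (csaps-style parameter
    ``p``; lam = (1-p)/p on a sample-index axis) tracks the artifact and
    is subtracted; the residual is re-anchored at the pre-segment level
    A.  When the level difference (A - B) across the run — A and B the
    mean levels of unflagged samples in windows of ``level_window_s``
    flanking it — exceeds ``relevel_thresh_od``, everything after the
    run is shifted by (A - B): that removes persistent step artifacts,
    while spike runs (whose flanking levels agree to within the
    haemodynamic signal scale, far below artifact amplitude) leave the
    rest of the series untouched instead of acquiring a spurious step.
    Runs shorter than 3 samples have their mean subtracted instead
    (logged).
    """
    if not (0 < p < 1):
        raise ValueError("spline parameter p must be in (0, 1)")
    if mask.shape != (od.dod.shape[0], od.dod.shape[2]):
        raise ValueError("mask shape does not match series")
    w = max(1, int(round(level_window_s * od.fs)))
    lam = (1.0 - p) / p
    out = od.dod.copy()
    for ci in range(out.shape[0]):
        runs = _runs(mask[ci])
        for wi in range(out.shape[1]):
            y = out[ci, wi]
            for i0, i1 in runs:
                seg = y[i0:i1]
                # level estimates exclude flagged samples (later artifacts
                # must not bias the step estimate of this run)
                pre_sl = slice(max(0, i0 - w), i0)
                post_sl = slice(i1, i1 + w)
                pre = y[pre_sl][~mask[ci, pre_sl]]
                post = y[post_sl][~mask[ci, post_sl]]
                if len(pre) == 0 and len(post) == 0:
                    continue  # fully flagged series: nothing to anchor to
                a = pre.mean() if len(pre) else post.mean()
                b = post.mean() if len(post) else a
                if len(seg) >= 3:
                    x = np.arange(len(seg), dtype=float)
                    fit = make_smoothing_spline(x, seg, lam=lam)(x)
                else:
                    logger.info("flagged run of %d samples: mean-subtracted",
                                len(seg))
                    fit = np.full(len(seg), seg.mean())
                y[i0:i1] = seg - fit + a
                if abs(a - b) > relevel_thresh_od:
                    y[i1:] += a - b
    return ODSeries(dod=out, fs=od.fs, layout=od.layout)


def wavelet_correct(od: ODSeries, alpha: float | None = 0.5,
                    wavelet: str = "db2",
                    protect_below_hz: float = 0.1) -> ODSeries:
    """IQR-threshold wavelet despiking.

    Per channel/wavelength the series is decomposed (symmetric-padded
    discrete wavelet transform, maximum dyadic depth); at each detail
    level, coefficients outside [Q1 - alpha*IQR, Q3 + alpha*IQR] are set
    to zero and the series reconstructed.  The step targets brief,
    large-amplitude artifacts, which live at fine scales; detail levels
    whose centre pseudo-frequency falls below ``protect_below_hz`` carry
    the slow haemodynamic response itself and are left untouched so that
    outlier removal cannot excise the signal of interest.  ``alpha=None``
    (or inf) disables zeroing and returns the identity up to
    reconstruction error.
    """
    c, w, t = od.dod.shape
    wav = pywt.Wavelet(wavelet)
    if t < wav.dec_len:
        raise ValueError("series shorter than wavelet support")
    out = np.empty_like(od.dod)
    for ci in range(c):
        for wi in range(w):
            y = od.dod[ci, wi]
            coeffs = pywt.wavedec(y, wav, mode="symmetric")
            n_detail = len(coeffs) - 1
            if alpha is not None and np.isfinite(alpha):
                for li, d in enumerate(coeffs[1:]):
                    # coeffs[1] is the coarsest detail level
                    level = n_detail - li
                    centre_hz = od.fs / 2.0 ** (level + 1) * 1.5
                    if centre_hz < protect_below_hz:
                        continue
                    q1, q3 = np.percentile(d, [25, 75])
                    iqr = q3 - q1
                    d[(d < q1 - alpha * iqr) | (d > q3 + alpha * iqr)] = 0.0
            rec = pywt.waverec(coeffs, wav, mode="symmetric")
            out[ci, wi] = rec[:t]
    return ODSeries(dod=out, fs=od.fs, layout=od.layout)


def bandpass(od: ODSeries, f_lo_hz: float = 0.01, f_hi_hz: float = 0.50,
             order: int = 3) -> ODSeries:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    nyq = od.fs / 2.0
    if not (0 < f_lo_hz < f_hi_hz < nyq):
        raise ValueError(f"invalid band ({f_lo_hz}, {f_hi_hz}) at fs={od.fs}")
    sos = signal.butter(order, [f_lo_hz, f_hi_hz], btype="bandpass",
                        fs=od.fs, output="sos")
    out = signal.sosfiltfilt(sos, od.dod, axis=-1)
    return ODSeries(dod=out, fs=od.fs, layout=od.layout)


def epoch_and_average(conc: ConcSeries, sched: StimulusSchedule,
                      mask: np.ndarray | None = None,
                      window_s: tuple = (-2.0, 25.0),
                      baseline_s: tuple = (-5.0, 0.0),
                      channel_keep: np.ndarray | None = None,
                      trial_reject_tol: float = 0.10,
                      return_trials: bool = False):
    """Extract per-block epochs, baseline-correct, reject contaminated
    trials, and average per condition.

    Baseline correction removes, per channel and trial, the mean of the
    ``baseline_s`` window of the continuous series.  A trial is rejected
    when the mean fraction of residually flagged samples across retained
    channels inside its epoch window exceeds ``trial_reject_tol``.

    Returns ``(EpochAverage, trial_log)`` — plus per-trial corrected
    epochs over the union window when ``return_trials`` is set.
    """
    fs = conc.fs
    n = conc.dhbo.shape[-1]
    if channel_keep is None:
        channel_keep = np.ones(conc.dhbo.shape[0], dtype=bool)
    chans = np.flatnonzero(channel_keep)
    lo = min(window_s[0], baseline_s[0])
    hi = window_s[1]
    i_lo, i_hi = int(round(lo * fs)), int(round(hi * fs))
    b0 = int(round(baseline_s[0] * fs))
    b1 = int(round(baseline_s[1] * fs))
    w0 = int(round(window_s[0] * fs))
    time_full = np.arange(i_lo, i_hi) / fs

    trials = {c: [] for c in np.unique(sched.condition)}
    log_rows = []
    for bi, (onset, dur, cond) in enumerate(sched.blocks()):
        i_on = int(round(onset * fs))
        if i_on + i_lo < 0 or i_on + i_hi > n:
            raise DataError(f"epoch of block {bi} extends outside the recording")
        sl = slice(i_on + i_lo, i_on + i_hi)
        base_sl = slice(i_on + b0, i_on + b1)
        hbo = conc.dhbo[chans, sl] - conc.dhbo[chans, base_sl].mean(axis=-1, keepdims=True)
        hbr = conc.dhbr[chans, sl] - conc.dhbr[chans, base_sl].mean(axis=-1, keepdims=True)
        if mask is not None and len(chans):
            frac = float(mask[chans, slice(i_on + w0, i_on + i_hi)].mean())
        else:
            frac = 0.0
        keep = frac <= trial_reject_tol
        log_rows.append({"block": bi, "condition": cond, "onset_s": onset,
                         "flagged_fraction": frac, "retained": keep})
        if keep:
            trials[cond].append((hbo, hbr))

    w_sl = slice(w0 - i_lo, i_hi - i_lo)
    dhbo, dhbr, n_trials = {}, {}, {}
    for cond, items in trials.items():
        n_trials[cond] = len(items)
        if items:
            dhbo[cond] = np.mean([h for h, _ in items], axis=0)[:, w_sl]
            dhbr[cond] = np.mean([r for _, r in items], axis=0)[:, w_sl]
        else:
            logger.warning("condition %r has zero retained trials", cond)
            dhbo[cond] = None
            dhbr[cond] = None
    ep = EpochAverage(time_s=time_full[w_sl], dhbo=dhbo, dhbr=dhbr,
                      n_trials=n_trials, channel_index=chans,
                      layout=conc.layout, fs=fs)
    trial_log = pd.DataFrame(log_rows)
    if return_trials:
        return ep, trial_log, trials, time_full
    return ep, trial_log


def assess_inclusion(channel_keep: np.ndarray, trial_log: pd.DataFrame,
                     min_channels: int = 18,
                     min_trial_fraction: float = 0.5) -> InclusionDecision:
    """Apply the subject inclusion rule: at least ``min_channels``
    retained channels and at least ``min_trial_fraction`` retained
    trials (boundary values included)."""
    n_ch = int(np.sum(channel_keep))
    frac = float(trial_log["retained"].mean()) if len(trial_log) else 0.0
    reasons = []
    if n_ch < min_channels:
        reasons.append(f"fewer than {min_channels} channels retained ({n_ch})")
    if frac < min_trial_fraction:
        reasons.append(f"fewer than {min_trial_fraction:.0%} trials retained "
                       f"({frac:.0%})")
    zero = [c for c, k in trial_log.groupby("condition")["retained"].sum().items()
            if k == 0] if len(trial_log) else []
    for c in zero:
        reasons.append(f"no retained trials in condition {c!r}")
    return InclusionDecision(retained_channels=n_ch,
                             retained_trial_fraction=frac,
                             included=not reasons, reasons=reasons)


@dataclass
class PreprocessResult:
    epochs: EpochAverage
    inclusion: InclusionDecision
    channel_keep: np.ndarray
    artifact_mask: np.ndarray
    trial_log: pd.DataFrame
    conc: ConcSeries


def preprocess_subject(rec: RawRecording, sched: StimulusSchedule,
                       cfg: PreprocessConfig | None = None) -> PreprocessResult:
    """Run the full chain on one subject's recording."""
    cfg = cfg or PreprocessConfig()
    od = intensity_to_od(rec)
    keep = prune_channels(rec, cfg.snr_thresh)
    if cfg.do_motion:
        mask = detect_motion(od, cfg.t_motion_s, cfg.t_mask_s,
                             cfg.std_thresh, cfg.amp_thresh)
    else:
        mask = np.zeros((rec.layout.n_channels, rec.n_samples), dtype=bool)
    if cfg.do_spline:
        od = spline_correct(od, mask, cfg.spline_p)
    if cfg.do_wavelet:
        od = wavelet_correct(od, cfg.wavelet_alpha, cfg.wavelet)
    if cfg.do_bandpass:
        od = bandpass(od, cfg.f_lo_hz, cfg.f_hi_hz, cfg.filter_order)
    dhbo, dhbr = od_to_conc(od.dod, rec.layout, cfg.extinction, cfg.age_years)
    conc = ConcSeries(dhbo=dhbo, dhbr=dhbr, fs=rec.fs, layout=rec.layout)
    ep, trial_log = epoch_and_average(
        conc, sched, mask=mask, window_s=cfg.window_s,
        baseline_s=cfg.baseline_s, channel_keep=keep,
        trial_reject_tol=cfg.trial_reject_tol)
    incl = assess_inclusion(keep, trial_log, cfg.min_channels,
                            cfg.min_trial_fraction)
    return PreprocessResult(epochs=ep, inclusion=incl, channel_keep=keep,
                            artifact_mask=mask, trial_log=trial_log, conc=conc)
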