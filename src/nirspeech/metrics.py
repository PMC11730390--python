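"""Per-subject speech-discrimination metrics.

SP is the absolute difference in mean haemodynamic (ΔHbO) changes
between the forward and reverse conditions over all retained channels;
SP_L and SP_R restrict to one hemisphere.  The laterality index
LI = ((SP_L - SP_R)/(SP_L + SP_R))*100 spans -100 (complete right
dominance) to +100 (complete left dominance).  Signed (algebraic)
variants without the absolute value support analyses split by response
sign, since about half of neonates show inverted HbO responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import EpochAverage
from .probe import ProbeLayout

RESPONSE_WINDOW_S = (0.0, 25.0)


@dataclass
class SubjectMetrics:
    subject_id: str
    sp: float | None
    sp_l: float | None
    sp_r: float | None
    li_sp: float | None          # None when undefined (SP_L + SP_R = 0)
    sign: str | None             # "pos" | "inv"
    signed_sp: float | None
    signed_sp_l: float | None
    signed_sp_r: float | None
    included: bool
    notes: list


def _window_slice(ep: EpochAverage, response_window_s) -> slice:
    lo, hi = response_window_s
    i0 = int(np.searchsorted(ep.time_s, lo - 1e-9))
    i1 = int(np.searchsorted(ep.time_s, hi - 1e-9))
    return slice(i0, i1)


def condition_mean(ep: EpochAverage, channels: np.ndarray,
                   response_window_s=RESPONSE_WINDOW_S) -> dict:
    """Time-mean of baseline-corrected ΔHbO over the response window,
    per channel and condition.

    ``channels`` are positions within ``ep.channel_index``.
    """
    channels = np.asarray(channels)
    if channels.size == 0:
        raise ValueError("empty channel subset")
    sl = _window_slice(ep, response_window_s)
    out = {}
    for cond, arr in ep.dhbo.items():
        out[cond] = None if arr is None else arr[channels, sl].mean(axis=-1)
    return out


def _hemi_positions(ep: EpochAverage, layout: ProbeLayout, hemi: str) -> np.ndarray:
    hemis = layout.hemisphere[ep.channel_index]
    return np.flatnonzero(hemis == hemi)


def _channel_diffs(ep: EpochAverage, response_window_s) -> np.ndarray:
    """Per-retained-channel forward-minus-reverse window means."""
    for cond in ("forward", "reverse"):
        if ep.dhbo.get(cond) is None:
            raise ValueError(f"condition {cond!r} average missing")
    all_pos = np.arange(len(ep.channel_index))
    means = condition_mean(ep, all_pos, response_window_s)
    return means["forward"] - means["reverse"]


def signed_discrimination(ep: EpochAverage, layout: ProbeLayout | None = None,
                          response_window_s=RESPONSE_WINDOW_S):
    """Algebraic (signed) discrimination: mean over channels of the
    forward-reverse difference, overall and per hemisphere.

    A hemisphere with no retained channels yields None for its value.
    """
    layout = layout or ep.layout
    diffs = _channel_diffs(ep, response_window_s)
    out = {"all": float(diffs.mean())}
    for hemi in ("L", "R"):
        pos = _hemi_positions(ep, layout, hemi)
        out[hemi] = float(diffs[pos].mean()) if pos.size else None
    return out["all"], out["L"], out["R"]


def speech_discrimination(ep: EpochAverage, layout: ProbeLayout | None = None,
                          response_window_s=RESPONSE_WINDOW_S,
                          abs_first: bool = False):
    """(SP, SP_L, SP_R): absolute difference in mean ΔHbO between
    conditions over all channels / per hemisphere.

    Default aggregation averages the per-channel differences first and
    then takes the absolute value; ``abs_first=True`` switches to
    per-channel absolute values before averaging (sensitivity variant).
    """
    layout = layout or ep.layout
    diffs = _channel_diffs(ep, response_window_s)
    if abs_first:
        diffs = np.abs(diffs)
    agg = (lambda d: float(np.mean(d))) if abs_first else \
        (lambda d: float(abs(np.mean(d))))
    sp = agg(diffs)
    out = {}
    for hemi in ("L", "R"):
        pos = _hemi_positions(ep, layout, hemi)
        out[hemi] = agg(diffs[pos]) if pos.size else None
    return sp, out["L"], out["R"]


def laterality_index(sp_l: float, sp_r: float) -> float:
    """LI = ((SP_L - SP_R)/(SP_L + SP_R))*100, in [-100, 100].

    Returns NaN (undefined) when both inputs are zero; callers exclude
    such subjects from laterality analyses.
    """
    if sp_l < 0 or sp_r < 0:
        raise ValueError("hemispheric metrics must be non-negative")
    total = sp_l + sp_r
    if total == 0:
        return float("nan")
    return (sp_l - sp_r) / total * 100.0


def response_sign(ep: EpochAverage, response_window_s=RESPONSE_WINDOW_S) -> str:
    """Classify a subject as positive or inverted responder.

    ``inv`` iff the all-channel mean ΔHbO over the response window in
    the forward condition is negative; an exactly zero mean classifies
    as ``pos`` (ambiguous, logged by callers).
    """
    if ep.dhbo.get("forward") is None:
        raise ValueError("forward-condition average missing")
    all_pos = np.arange(len(ep.channel_index))
    m = condition_mean(ep, all_pos, response_window_s)["forward"].mean()
    return "inv" if m < 0 else "pos"


def compute_subject_metrics(ep: EpochAverage, included: bool = True,
                            layout: ProbeLayout | None = None,
                            response_window_s=RESPONSE_WINDOW_S,
                            abs_first: bool = False,
                            subject_id: str = "subject") -> SubjectMetrics:
    """Assemble the full per-subject metric set from a block average."""
    layout = layout or ep.layout
    notes = []
    try:
        sp, sp_l, sp_r = speech_discrimination(ep, layout, response_window_s,
                                               abs_first)
        ssp, ssp_l, ssp_r = signed_discrimination(ep, layout, response_window_s)
        sign = response_sign(ep, response_window_s)
    except ValueError as exc:
        notes.append(str(exc))
        return SubjectMetrics(subject_id, None, None, None, None, None,
                              None, None, None, False, notes)
    if sp_l is None or sp_r is None:
        notes.append("hemisphere with zero retained channels; LI skipped")
        li = None
    else:
        li = laterality_index(sp_l, sp_r)
        if np.isnan(li):
            notes.append("LI undefined (SP_L + SP_R = 0)")
            li = None
    return SubjectMetrics(subject_id=subject_id, sp=sp, sp_l=sp_l, sp_r=sp_r,
                          li_sp=li, sign=sign, signed_sp=ssp,
                          signed_sp_l=ssp_l, signed_sp_r=ssp_r,
                          included=included, notes=notes)
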