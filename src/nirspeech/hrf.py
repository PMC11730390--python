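"""Canonical haemodynamic response kernel and block responses.

A single-gamma kernel is used: downstream analysis only takes window
means of block averages, so the exact kernel shape is immaterial as
long as it is causal and smooth.  Time-to-peak defaults to 7 s, which
is in the range reported for neonatal auditory responses.
"""

from __future__ import annotations

import numpy as np
from scipy import signal, stats


def gamma_kernel(fs: float, peak_s: float = 7.0, shape: float = 8.0,
                 duration_s: float = 30.0) -> np.ndarray:
    """Causal single-gamma impulse response, unit peak, sampled at fs.

    The default shape makes the response resolve within ~15 s of
    stimulus offset, consistent with a block paradigm whose silences
    (15-30 s) are sized for the response to return to baseline before
    the next block.
    """
    t = np.arange(0.0, duration_s, 1.0 / fs)
    scale = peak_s / (shape - 1.0)  # mode of gamma pdf = (shape-1)*scale
    k = stats.gamma.pdf(t, a=shape, scale=scale)
    return k / k.max()


def single_block_window_mean(fs: float, duration_s: float, kernel: np.ndarray,
                             window_s: tuple = (0.0, 25.0)) -> float:
    """Window mean of one isolated peak-normalised block response.

    Used to calibrate designed amplitudes so that the analysis-side
    window-mean metric recovers them on their own scale."""
    single = signal.fftconvolve(np.ones(int(round(duration_s * fs))), kernel)
    peak = single.max()
    i0, i1 = int(round(window_s[0] * fs)), int(round(window_s[1] * fs))
    padded = np.zeros(max(i1, len(single)))
    padded[:len(single)] = single
    return float(padded[i0:i1].mean() / peak)


def block_response(n_samples: int, fs: float, onsets_s, duration_s: float,
                   kernel: np.ndarray,
                   window_s: tuple = (0.0, 25.0)) -> np.ndarray:
    """Boxcar-convolved response of a set of blocks.

    Normalised so that the mean of one isolated block's response over
    ``window_s`` (relative to its onset) is 1: a designed amplitude a
    then appears as a window-mean concentration change of a.
    """
    box = np.zeros(n_samples)
    for onset in np.atleast_1d(onsets_s):
        i0 = int(round(onset * fs))
        i1 = min(int(round((onset + duration_s) * fs)), n_samples)
        if i0 < n_samples:
            box[i0:i1] = 1.0
    resp = signal.fftconvolve(box, kernel)[:n_samples]
    single = signal.fftconvolve(np.ones(int(round(duration_s * fs))), kernel)
    peak = single.max()
    wmean = single_block_window_mean(fs, duration_s, kernel, window_s)
    return resp / (peak * wmean)
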