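import numpy as np
import pytest

from nirspeech import (NoiseConfig, PreprocessConfig, designed_truth,
                       default_layout, make_schedule, preprocess_subject,
                       simulate_subject)
from nirspeech.preprocess import EpochAverage

PASSTHROUGH = PreprocessConfig(do_motion=False, do_spline=False,
                               do_wavelet=False, do_bandpass=False)


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def noise_free_subject():
    """Noise-free subject whose blocks are separated widely enough that
    each response fully resolves before the next baseline window."""
    truth = designed_truth("nf01", sp=0.10, li=25.0)
    sched = make_schedule(4, 15.0, (40.0, 45.0), 2, seed=2)
    rec = simulate_subject(truth, sched=sched, noise=NoiseConfig.none())
    return truth, sched, rec


@pytest.fixture(scope="session")
def noise_free_result(noise_free_subject):
    truth, sched, rec = noise_free_subject
    return preprocess_subject(rec, sched, PASSTHROUGH)


def make_epochs(diffs_l, diffs_r, layout=None, fs=10.0, reverse_level=0.0):
    """Synthetic EpochAverage whose per-channel forward-reverse window-mean
    differences are exactly the given values (left channels first)."""
    layout = layout or default_layout(n_per_hemisphere=max(len(diffs_l),
                                                           len(diffs_r)))
    time_s = np.arange(-2.0, 25.0, 1.0 / fs)
    n = len(time_s)
    n_l = layout.channels_in("L")[:len(diffs_l)]
    n_r = layout.channels_in("R")[:len(diffs_r)]
    chans = np.concatenate([n_l, n_r])
    rev = np.full((len(chans), n), reverse_level)
    fwd = rev + np.array(list(diffs_l) + list(diffs_r))[:, None]
    return EpochAverage(time_s=time_s,
                        dhbo={"forward": fwd, "reverse": rev},
                        dhbr={"forward": -0.3 * fwd, "reverse": -0.3 * rev},
                        n_trials={"forward": 10, "reverse": 10},
                        channel_index=chans, layout=layout, fs=fs)
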