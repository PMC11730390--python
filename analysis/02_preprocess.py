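#!/usr/bin/env python
"""Run the preprocessing chain on every simulated recording.

Optical density, SNR channel pruning, motion detection, spline and
wavelet correction, 0.01-0.50 Hz band-pass, modified Beer-Lambert and
block averaging over [-2, 25) s with a [-5, 0) s baseline.  Writes
per-subject block averages to scratch/epochs and the inclusion log
(channels retained, trial fraction, exclusion reasons) to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from nirspeech.io import read_schedule_csv, read_snirf, write_epochs_csv
from nirspeech.preprocess import PreprocessConfig, preprocess_subject

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.parse_args()

    rec_dir = ROOT / "scratch" / "recordings"
    ep_dir = ROOT / "scratch" / "epochs"
    ep_dir.mkdir(parents=True, exist_ok=True)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    cfg = PreprocessConfig()
    rows = []
    for path in sorted(rec_dir.glob("*.snirf")):
        rec, sched = read_snirf(path)
        if sched is None:
            sched = read_schedule_csv(path.with_name(path.stem
                                                     + "_schedule.csv"))
        res = preprocess_subject(rec, sched, cfg)
        write_epochs_csv(ep_dir / f"{rec.subject_id}.csv", res.epochs,
                         rec.subject_id)
        rows.append({"subject_id": rec.subject_id,
                     "included": res.inclusion.included,
                     "retained_channels": res.inclusion.retained_channels,
                     "retained_trial_fraction":
                         round(res.inclusion.retained_trial_fraction, 3),
                     "reasons": "; ".join(res.inclusion.reasons)})
    log = pd.DataFrame(rows)
    log.to_csv(results / "inclusion_log.csv", index=False)

    n_out = int((~log["included"]).sum())
    print(f"preprocessed {len(log)} subjects; excluded {n_out}")
    print(f"mean retained channels: {log['retained_channels'].mean():.2f}")
    print(f"mean retained trial fraction: "
          f"{log['retained_trial_fraction'].mean():.3f}")
    if n_out:
        print(log[~log["included"]][["subject_id", "reasons"]]
              .to_string(index=False))
    print(f"epochs -> {ep_dir}")


if __name__ == "__main__":
    main()
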