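"""File formats: SNIRF (HDF5) recordings and plain CSV dialects.

CSV dialects are UTF-8, comma-separated, header row, "." decimal:
  * intensity: long format with channel_id, wavelength_nm, time_s, intensity
  * schedule: onset_s, duration_s, condition
  * cohort / metrics: one row per subject
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .preprocess import RawRecording
from .probe import ProbeLayout
from .schedule import StimulusSchedule


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# SNIRF
# ---------------------------------------------------------------------------

def write_snirf(path, rec: RawRecording, sched: StimulusSchedule | None = None):
    """Write a recording as a continuous-wave SNIRF file.

    Measurement list order is channel-major, wavelength-minor, matching
    the (C, W, T) intensity array.
    """
    layout = rec.layout
    c, w, t = rec.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        data = nirs.create_group("data1")
        dts = rec.intensity.reshape(c * w, t).T  # (T, M)
        data.create_dataset("dataTimeSeries", data=dts)
        data.create_dataset("time", data=np.arange(t) / rec.fs)
        m = 1
        for ci in range(c):
            for wi in range(w):
                ml = data.create_group(f"measurementList{m}")
                ml.create_dataset("sourceIndex", data=int(layout.source_id[ci]))
                ml.create_dataset("detectorIndex", data=int(layout.detector_id[ci]))
                ml.create_dataset("wavelengthIndex", data=wi + 1)
                ml.create_dataset("dataType", data=1)          # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                m += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(layout.wavelengths_nm))
        n_src = int(layout.source_id.max())
        n_det = int(layout.detector_id.max())
        # nominal positions: hemispheres at x = -/+ distance, sources on a line
        probe.create_dataset("sourcePos2D",
                             data=np.column_stack([np.zeros(n_src),
                                                   np.arange(n_src, dtype=float)]))
        probe.create_dataset("detectorPos2D",
                             data=np.column_stack([
                                 np.full(n_det, layout.distance_cm),
                                 np.arange(n_det, dtype=float)]))
        aux = nirs.create_group("nirspeech")   # custom: hemisphere labels
        aux.create_dataset("hemisphere",
                           data=np.array(layout.hemisphere, dtype="S1"))
        aux.create_dataset("channel_id", data=layout.channel_id)
        aux.create_dataset("distance_cm", data=layout.distance_cm)
        if sched is not None:
            for si, cond in enumerate(sorted(set(sched.condition))):
                stim = nirs.create_group(f"stim{si + 1}")
                stim.create_dataset("name", data=str(cond))
                rows = [(o, d, 1.0) for o, d, cc in sched.blocks()
                        if cc == cond]
                stim.create_dataset("data", data=np.asarray(rows))


def read_snirf(path):
    """Read a SNIRF file written by :func:`write_snirf`.

    Returns (RawRecording, StimulusSchedule or None)."""
    with h5py.File(path, "r") as f:
        try:
            nirs = f["nirs"]
            data = nirs["data1"]
            dts = np.asarray(data["dataTimeSeries"])
            time = np.asarray(data["time"])
            wavelengths = tuple(np.asarray(nirs["probe/wavelengths"]).tolist())
            aux = nirs["nirspeech"]
            hemisphere = np.array([s.decode() for s in aux["hemisphere"][()]])
            channel_id = np.asarray(aux["channel_id"])
            distance_cm = float(aux["distance_cm"][()])
            sid = nirs["metaDataTags/SubjectID"][()]
            if isinstance(sid, bytes):
                sid = sid.decode()
            n_ml = sum(1 for k in data if k.startswith("measurementList"))
            src, det = [], []
            for m in range(1, n_ml + 1, len(wavelengths)):
                ml = data[f"measurementList{m}"]
                src.append(int(ml["sourceIndex"][()]))
                det.append(int(ml["detectorIndex"][()]))
        except KeyError as exc:
            raise ParseError(f"{path}: missing SNIRF field {exc}") from exc
        c = len(channel_id)
        w = len(wavelengths)
        fs = 1.0 / float(np.median(np.diff(time)))
        layout = ProbeLayout(channel_id=channel_id, source_id=np.asarray(src),
                             detector_id=np.asarray(det), hemisphere=hemisphere,
                             distance_cm=distance_cm, wavelengths_nm=wavelengths)
        rec = RawRecording(intensity=dts.T.reshape(c, w, -1), fs=fs,
                           layout=layout, subject_id=str(sid))
        sched = None
        stims = sorted(k for k in nirs if k.startswith("stim"))
        if stims:
            rows = []
            for k in stims:
                name = nirs[k]["name"][()]
                if isinstance(name, bytes):
                    name = name.decode()
                for o, d, _ in np.atleast_2d(np.asarray(nirs[k]["data"])):
                    rows.append((float(o), float(d), str(name)))
            rows.sort()
            sched = StimulusSchedule(
                onset_s=np.array([r[0] for r in rows]),
                duration_s=np.array([r[1] for r in rows]),
                condition=np.array([r[2] for r in rows]))
    return rec, sched


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def write_intensity_csv(path, rec: RawRecording):
    c, w, t = rec.intensity.shape
    time = np.arange(t) / rec.fs
    frames = []
    for ci in range(c):
        for wi in range(w):
            frames.append(pd.DataFrame({
                "channel_id": rec.layout.channel_id[ci],
                "wavelength_nm": rec.layout.wavelengths_nm[wi],
                "time_s": time,
                "intensity": rec.intensity[ci, wi],
            }))
    pd.concat(frames).to_csv(path, index=False)


def read_intensity_csv(path, layout: ProbeLayout, subject_id="subject") -> RawRecording:
    df = pd.read_csv(path)
    need = {"channel_id", "wavelength_nm", "time_s", "intensity"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    t = df["time_s"].nunique()
    fs = 1.0 / float(np.median(np.diff(np.sort(df["time_s"].unique()))))
    arr = np.empty((layout.n_channels, layout.n_wavelengths, t))
    for ci, ch in enumerate(layout.channel_id):
        for wi, lam in enumerate(layout.wavelengths_nm):
            sub = df[(df["channel_id"] == ch) & (df["wavelength_nm"] == lam)]
            if len(sub) != t:
                raise ParseError(f"{path}: channel {ch} @ {lam} nm has "
                                 f"{len(sub)} samples, expected {t}")
            arr[ci, wi] = sub.sort_values("time_s")["intensity"].to_numpy()
    return RawRecording(intensity=arr, fs=fs, layout=layout, subject_id=subject_id)


def write_schedule_csv(path, sched: StimulusSchedule):
    pd.DataFrame({"onset_s": sched.onset_s, "duration_s": sched.duration_s,
                  "condition": sched.condition}).to_csv(path, index=False)


def read_schedule_csv(path) -> StimulusSchedule:
    df = pd.read_csv(path)
    need = {"onset_s", "duration_s", "condition"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    onsets = df["onset_s"].to_numpy(float)
    if np.any(np.diff(onsets) <= 0):
        raise ParseError(f"{path}: block onsets must be strictly increasing")
    return StimulusSchedule(onset_s=onsets,
                            duration_s=df["duration_s"].to_numpy(float),
                            condition=df["condition"].to_numpy(str))


def write_epochs_csv(path, ep, subject_id="subject"):
    """Tidy per-subject block averages: subject, condition, channel_id,
    time_s, dHbO, dHbR."""
    frames = []
    for cond, arr in ep.dhbo.items():
        if arr is None:
            continue
        for row, ch_pos in enumerate(ep.channel_index):
            frames.append(pd.DataFrame({
                "subject": subject_id, "condition": cond,
                "channel_id": ep.layout.channel_id[ch_pos],
                "time_s": ep.time_s, "dHbO": arr[row],
                "dHbR": ep.dhbr[cond][row]}))
    pd.concat(frames).to_csv(path, index=False)


def read_epochs_csv(path, layout):
    """Inverse of :func:`write_epochs_csv` (requires the probe layout)."""
    from .preprocess import EpochAverage
    df = pd.read_csv(path)
    need = {"subject", "condition", "channel_id", "time_s", "dHbO", "dHbR"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    time_s = np.sort(df["time_s"].unique())
    fs = 1.0 / float(np.median(np.diff(time_s)))
    chan_ids = np.sort(df["channel_id"].unique())
    id_to_pos = {cid: pos for pos, cid in enumerate(layout.channel_id)}
    chans = np.array([id_to_pos[c] for c in chan_ids])
    dhbo, dhbr = {}, {}
    for cond, sub in df.groupby("condition"):
        piv_o = sub.pivot_table(index="channel_id", columns="time_s",
                                values="dHbO").loc[chan_ids, time_s]
        piv_r = sub.pivot_table(index="channel_id", columns="time_s",
                                values="dHbR").loc[chan_ids, time_s]
        dhbo[cond] = piv_o.to_numpy()
        dhbr[cond] = piv_r.to_numpy()
    return EpochAverage(time_s=time_s, dhbo=dhbo, dhbr=dhbr,
                        n_trials={c: -1 for c in dhbo},
                        channel_index=chans, layout=layout, fs=fs)


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(path, cfg: dict):
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True), encoding="utf-8")
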