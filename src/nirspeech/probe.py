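"""Bilateral fNIRS probe geometry.

The default layout mirrors a neonatal two-pad montage: 24 measurement
channels, 12 per hemisphere, two continuous-wave wavelengths (695 and
830 nm) per channel.  Geometry here is purely bookkeeping — channel to
hemisphere assignment and source–detector separation — no scalp
registration is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_WAVELENGTHS = (695.0, 830.0)


@dataclass(frozen=True)
class ProbeLayout:
    """Channel table of a bilateral probe.

    Parameters
    ----------
    channel_id, source_id, detector_id
        Integer arrays, one entry per channel.
    hemisphere
        Array of ``"L"``/``"R"`` labels per channel.
    distance_cm
        Source–detector separation in cm (shared by all channels).
    wavelengths_nm
        The two laser wavelengths in nm.
    """

    channel_id: np.ndarray
    source_id: np.ndarray
    detector_id: np.ndarray
    hemisphere: np.ndarray
    distance_cm: float = 3.0
    wavelengths_nm: tuple = field(default=DEFAULT_WAVELENGTHS)

    def __post_init__(self):
        n = len(self.channel_id)
        for name in ("source_id", "detector_id", "hemisphere"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != channel count")
        if self.distance_cm <= 0:
            raise ValueError("source-detector distance must be positive")
        if len(set(self.wavelengths_nm)) != len(self.wavelengths_nm):
            raise ValueError("wavelengths must be distinct")
        if not np.all(np.isin(self.hemisphere, ["L", "R"])):
            raise ValueError("hemisphere labels must be 'L' or 'R'")

    @property
    def n_channels(self) -> int:
        return len(self.channel_id)

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths_nm)

    def channels_in(self, hemisphere: str) -> np.ndarray:
        """Channel indices (positional) in one hemisphere."""
        return np.flatnonzero(self.hemisphere == hemisphere)


def default_layout(n_per_hemisphere: int = 12, distance_cm: float = 3.0,
                   wavelengths_nm: tuple = DEFAULT_WAVELENGTHS) -> ProbeLayout:
    """Default 24-channel bilateral layout (12 channels per hemisphere)."""
    n = 2 * n_per_hemisphere
    channel_id = np.arange(1, n + 1)
    # simple serpentine source/detector numbering, one pad per hemisphere
    source_id = (channel_id + 1) // 2
    detector_id = (channel_id // 2) + 1
    hemisphere = np.array(["L"] * n_per_hemisphere + ["R"] * n_per_hemisphere)
    return ProbeLayout(channel_id=channel_id, source_id=source_id,
                       detector_id=detector_id, hemisphere=hemisphere,
                       distance_cm=distance_cm, wavelengths_nm=tuple(wavelengths_nm))
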