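"""Sensor geometry helpers.

Positions come from MNE's built-in idealized montages (extended 10-20
system on a spherical head). The default 64-channel layout matches a
standard 64-electrode research cap.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

# 64 electrodes of the extended international 10-20 system, in a common
# amplifier ordering (frontal-polar to inion).
CAP64 = [
    "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3", "T7", "TP9",
    "CP5", "CP1", "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8",
    "TP10", "CP6", "CP2", "Cz", "C4", "T8", "FT10", "FC6", "FC2", "F4",
    "F8", "Fp2", "AF7", "AF3", "AFz", "F1", "F5", "FT7", "FC3", "C1",
    "C5", "TP7", "CP3", "P1", "P5", "PO7", "PO3", "POz", "PO4", "PO8",
    "P6", "P2", "CPz", "CP4", "TP8", "C6", "C2", "FC4", "FT8", "F6",
    "AF8", "AF4", "F2", "Iz",
]

_MONTAGE_ALIASES = {
    "standard-10-20": "standard_1020",
    "standard_1020": "standard_1020",
    "standard-10-05": "standard_1005",
    "standard_1005": "standard_1005",
}


@lru_cache(maxsize=8)
def _montage_positions(montage: str) -> dict:
    import mne

    mne.set_log_level("ERROR")
    m = mne.channels.make_standard_montage(_MONTAGE_ALIASES[montage])
    return m.get_positions()["ch_pos"]


def channel_positions(
    ch_names: list[str] | None = None, montage: str = "standard-10-20"
) -> tuple[list[str], np.ndarray]:
    """Return (channel names, n x 3 positions on the unit sphere).

    Parameters
    ----------
    ch_names
        Electrode labels; defaults to the 64-channel cap. Labels must exist
        in the named montage.
    montage
        Montage name; ``"standard-10-20"`` (extended, idealized) by default.
    """
    if montage not in _MONTAGE_ALIASES:
        raise ValueError(f"unknown montage name: {montage!r}")
    if ch_names is None:
        ch_names = list(CAP64)
    pos_map = _montage_positions(montage)
    missing = [c for c in ch_names if c not in pos_map]
    if missing:
        raise ValueError(f"channels not in montage {montage!r}: {missing}")
    pos = np.asarray([pos_map[c] for c in ch_names], dtype=float)
    # center on the head sphere and normalize to unit radius
    pos = pos - pos.mean(axis=0)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return list(ch_names), pos


def flat_positions(pos3d: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection of unit-sphere sensors to 2-D.

    x is right(+)/left(-), y anterior(+)/posterior(-); vertex maps to the
    origin. Used to build smooth archetype topographies.
    """
    x, y, z = pos3d[:, 0], pos3d[:, 1], pos3d[:, 2]
    theta = np.arccos(np.clip(z, -1.0, 1.0))  # polar angle from vertex
    phi = np.arctan2(y, x)
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])
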