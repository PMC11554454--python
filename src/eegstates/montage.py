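"""Standard scalp montages and electrode geometry.

Electrode coordinates come from the idealized 10-20 / 10-10 head model
bundled with MNE-Python.  Two fixed channel sets are provided: the
classic 19-electrode 10-20 array and a 60-electrode 10-10 array of the
kind used by modern high-density clinical amplifiers.
"""
from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

# Classic 10-20 array (19 scalp electrodes).
TEN_TWENTY_19 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
]

# 60-electrode 10-10 array (mastoids/earlobes and the inion excluded).
TEN_TEN_60 = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "O2",
]


@lru_cache(maxsize=4)
def _standard_positions_table() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1020")
    return {name: np.asarray(xyz, dtype=float)
            for name, xyz in montage.get_positions()["ch_pos"].items()}


def standard_positions(ch_names: list[str]) -> np.ndarray:
    """3-D head coordinates (meters) for standard 10-20/10-10 labels.

    Raises ``KeyError`` for labels absent from the standard montage.
    """
    table = _standard_positions_table()
    try:
        return np.stack([table[name] for name in ch_names])
    except KeyError as err:
        raise KeyError(f"channel {err} not in the standard 10-20 montage") from None


def planar_positions(positions: np.ndarray) -> np.ndarray:
    """Project 3-D electrode coordinates to the 2-D scalp plane.

    Uses the (x, y) plane directly (x: left->right, y: posterior->anterior),
    which is adequate for the smooth gradient maps and distance weights
    used in this package.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] not in (2, 3):
        raise ValueError("positions must be (n_channels, 2|3)")
    return positions[:, :2].copy()


def standard_channel_set(n_channels: int) -> list[str]:
    """Return the built-in channel set of the requested size (19 or 60)."""
    if n_channels == 19:
        return list(TEN_TWENTY_19)
    if n_channels == 60:
        return list(TEN_TEN_60)
    raise ValueError("built-in channel sets exist for 19 and 60 channels")
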