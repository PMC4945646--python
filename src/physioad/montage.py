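"""The 30-channel 10-20 montage used throughout the package."""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "CHANNELS",
    "FRONTAL",
    "LEFT_FRONTAL",
    "RIGHT_FRONTAL",
    "channel_positions",
    "frontal_indices",
]

#: the thirty recording electrodes (10-20 system)
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CPz", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

#: frontal sites entering GFP computation
FRONTAL: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
)

#: asymmetric frontal pairs for the pleasantness (hemispheric) contrast
LEFT_FRONTAL: tuple[str, ...] = ("Fp1", "F7", "F3", "FC5", "FC1")
RIGHT_FRONTAL: tuple[str, ...] = ("Fp2", "F8", "F4", "FC6", "FC2")


@lru_cache(maxsize=1)
def channel_positions() -> dict[str, np.ndarray]:
    """3-D electrode coordinates (meters) from the standard 10-20 template."""
    import warnings

    from mne.channels import make_standard_montage

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        mont = make_standard_montage("standard_1020")
    pos = mont.get_positions()["ch_pos"]
    lookup = {k.upper(): np.asarray(v, float) for k, v in pos.items()}
    return {ch: lookup[ch.upper()] for ch in CHANNELS}


def frontal_indices(channels: tuple[str, ...] = CHANNELS) -> np.ndarray:
    upper = [c.upper() for c in channels]
    return np.array([upper.index(f.upper()) for f in FRONTAL])


def indices_of(names: tuple[str, ...], channels: tuple[str, ...] = CHANNELS) -> np.ndarray:
    upper = [c.upper() for c in channels]
    return np.array([upper.index(n.upper()) for n in names])
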