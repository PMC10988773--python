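"""Electrode montage: the 68-channel Biosemi layout used throughout.

The cap is the 64-channel Biosemi ActiveTwo arrangement (standard 10-20
positions) extended with a posterior row of four electrodes (PO9, I1, I2,
PO10).  Positions are taken from MNE's standard 10-05 montage and projected
onto the unit sphere, which is all the inverse-distance channel
interpolation needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: Biosemi ActiveTwo 64-channel labels in cap order (A1..B32 ring mapping).
BIOSEMI64 = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]

#: Extra posterior row completing the 68-channel set.
POSTERIOR_ROW = ["PO9", "I1", "I2", "PO10"]

#: Full 68-channel layout.
CHANNELS_68 = BIOSEMI64 + POSTERIOR_ROW


@dataclass
class Montage:
    """Channel name -> 3-D unit-sphere position.

    Positions are unit vectors from the head-sphere centre, so Euclidean
    distance between them is a monotone proxy for angular (scalp) distance.
    """

    positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, p in self.positions.items():
            p = np.asarray(p, dtype=float)
            n = np.linalg.norm(p)
            if n == 0:
                raise ConfigurationError(f"zero-length position for {name}")
            self.positions[name] = p / n

    @property
    def channel_names(self) -> list[str]:
        return list(self.positions)

    def __contains__(self, name: str) -> bool:
        return name in self.positions

    def __getitem__(self, name: str) -> np.ndarray:
        return self.positions[name]

    def k_nearest(self, name: str, candidates: list[str], k: int) -> list[tuple[str, float]]:
        """The ``k`` candidates nearest to ``name``, as (channel, distance)."""
        if name not in self.positions:
            raise ConfigurationError(f"channel {name!r} not in montage")
        p = self.positions[name]
        dists = sorted(
            (float(np.linalg.norm(self.positions[c] - p)), c)
            for c in candidates
            if c != name and c in self.positions
        )
        if len(dists) < k:
            raise ConfigurationError(
                f"need {k} neighbours for {name!r}, only {len(dists)} available"
            )
        return [(c, d) for d, c in dists[:k]]


def standard_montage(channels: list[str] | None = None) -> Montage:
    """Build the 68-channel montage (or a subset) from MNE's 10-05 positions."""
    import warnings

    import mne

    channels = list(channels) if channels is not None else list(CHANNELS_68)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        try:
            std = mne.channels.make_standard_montage("colin27_1005")
        except ValueError:  # older MNE
            std = mne.channels.make_standard_montage("standard_1005")
    pos = std.get_positions()["ch_pos"]
    missing = [c for c in channels if c not in pos]
    if missing:
        raise ConfigurationError(f"channels missing from standard montage: {missing}")
    # Sphere centre estimated from the full cap so subsets keep consistent geometry.
    centre = np.mean([pos[c] for c in CHANNELS_68], axis=0)
    return Montage({c: np.asarray(pos[c], dtype=float) - centre for c in channels})
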