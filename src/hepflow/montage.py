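"""Electrode montage for the 23-channel clinical 10/20 layout.

The study montage is the international 10/20 scalp placement plus the
inferior temporal pair T9/T10 (23 scalp electrodes in total, legacy
temporal naming T3/T4/T5/T6).  Positions are idealized unit-sphere
coordinates (head center at the origin, +x right, +y anterior, +z up),
derived once from the standard 10/05 electrode description and frozen
here so the layout is a package constant rather than a runtime lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: unit-sphere (x, y, z) per channel; +x right, +y front, +z vertex
CHANNEL_POSITIONS: dict[str, tuple[float, float, float]] = {
    "Fp1": (-0.288733, +0.953152, -0.090196),
    "Fp2": (+0.278221, +0.956247, -0.090464),
    "F3": (-0.540358, +0.727871, +0.422158),
    "F4": (+0.540504, +0.737097, +0.405639),
    "C3": (-0.728655, +0.042369, +0.683570),
    "C4": (+0.734807, +0.050546, +0.676391),
    "P3": (-0.543469, -0.641061, +0.541924),
    "P4": (+0.551714, -0.632900, +0.543184),
    "O1": (-0.295693, -0.953194, +0.063142),
    "O2": (+0.288287, -0.955463, +0.063098),
    "F7": (-0.765757, +0.625547, -0.149355),
    "F8": (+0.761491, +0.630180, -0.151672),
    "T3": (-0.990506, -0.006394, -0.137323),
    "T4": (+0.990186, +0.005288, -0.139654),
    "T5": (-0.782408, -0.620552, -0.052464),
    "T6": (+0.781386, -0.621751, -0.053488),
    "Fz": (-0.003660, +0.756046, +0.654508),
    "Cz": (-0.002749, +0.064306, +0.997926),
    "Pz": (-0.003336, -0.633383, +0.773831),
    "Fpz": (-0.005377, +0.999194, -0.039768),
    "Oz": (-0.005618, -0.992489, +0.122208),
    "T9": (-0.862896, -0.003565, -0.505370),
    "T10": (+0.858562, -0.009004, -0.512631),
}

DEFAULT_CHANNELS: tuple[str, ...] = tuple(CHANNEL_POSITIONS)


@dataclass(frozen=True)
class MontageLayout:
    """Set of electrode labels with unit-sphere scalp positions.

    Parameters
    ----------
    labels
        Ordered channel labels; the order fixes the row order of every
        channels-by-time matrix in the pipeline.
    positions
        ``(n_channels, 3)`` array of unit vectors on the scalp sphere.
    """

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ValueError(
                f"positions shape {pos.shape} does not match "
                f"{len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("positions must lie on the unit sphere")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def indices(self, labels) -> np.ndarray:
        return np.array([self.index(lb) for lb in labels], dtype=int)

    def projection_2d(self) -> np.ndarray:
        """Azimuthal-equidistant projection from the vertex.

        Polar angle from Cz becomes the radius, so distances along the
        scalp are approximately preserved; used for Delaunay-based
        neighbor construction and topographic plots.
        """
        x, y, z = self.positions.T
        theta = np.arccos(np.clip(z, -1.0, 1.0))
        azimuth = np.arctan2(y, x)
        return np.column_stack([theta * np.cos(azimuth), theta * np.sin(azimuth)])

    def chord_distances(self) -> np.ndarray:
        """Pairwise 3-D chord distances between electrodes."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(diff, axis=-1)

    def subset(self, labels) -> "MontageLayout":
        idx = self.indices(labels)
        return MontageLayout(tuple(labels), self.positions[idx])


def default_montage() -> MontageLayout:
    """The study's 23-channel 10/20 + T9/T10 layout."""
    return MontageLayout(
        DEFAULT_CHANNELS,
        np.array([CHANNEL_POSITIONS[ch] for ch in DEFAULT_CHANNELS]),
    )
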