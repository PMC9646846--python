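"""Electrode montage handling: 3D scalp positions and their 2D polar projection.

Topographic EEG images need every electrode mapped to a point in the image
plane.  Positions on (or normalised to) the unit sphere are flattened with an
azimuthal-equidistant ("polar") projection about the vertex: a point at polar
angle ``theta`` and azimuth ``phi`` lands at radius ``theta`` (radians) along
azimuth ``phi``, so the vertex maps to the origin and angular distance from
the vertex is preserved along every meridian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MontageLayout", "project_montage", "default_layout"]


def project_montage(positions_3d: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection of unit-sphere electrode positions.

    Parameters
    ----------
    positions_3d : (n, 3) array
        Electrode coordinates; they are normalised to the unit sphere first.

    Returns
    -------
    (n, 2) array of planar coordinates.  An electrode at the vertex (0, 0, 1)
    maps to (0, 0); an equatorial electrode to radius pi/2.
    """
    pos = np.asarray(positions_3d, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError(f"expected (n, 3) positions, got {pos.shape}")
    norms = np.linalg.norm(pos, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm electrode position cannot be projected")
    unit = pos / norms[:, None]
    theta = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))  # polar angle from vertex
    phi = np.arctan2(unit[:, 1], unit[:, 0])
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


@dataclass
class MontageLayout:
    """Channel names with 3D positions and their deterministic 2D projection."""

    channel_names: list[str]
    positions_3d: np.ndarray
    positions_2d: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.positions_3d = np.asarray(self.positions_3d, dtype=float)
        if len(self.channel_names) != self.positions_3d.shape[0]:
            raise ValueError("one 3D position required per channel name")
        self.positions_2d = project_montage(self.positions_3d)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.positions_3d, columns=["x", "y", "z"])
        df.insert(0, "channel_name", self.channel_names)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MontageLayout":
        df = pd.read_csv(path)
        return cls(
            channel_names=[str(c) for c in df["channel_name"]],
            positions_3d=df[["x", "y", "z"]].to_numpy(),
        )

    def reorder(self, permutation: np.ndarray) -> "MontageLayout":
        """Layout with channels permuted; used to check permutation safety."""
        perm = np.asarray(permutation)
        return MontageLayout(
            channel_names=[self.channel_names[i] for i in perm],
            positions_3d=self.positions_3d[perm],
        )


def default_layout(n_channels: int = 62) -> MontageLayout:
    """Deterministic synthetic cap: a Fibonacci lattice on the upper hemisphere.

    Stands in for a real 62-electrode montage (the two EOG channels of a
    64-channel cap are conventionally dropped before analysis); spacing is
    approximately uniform, which is all the interpolation stage needs.
    """
    golden = (1 + np.sqrt(5)) / 2
    k = np.arange(n_channels)
    # z from just below the vertex down to ~15 degrees above the equator
    z = 1.0 - (k + 0.5) / n_channels * (1.0 - np.sin(np.deg2rad(15.0)))
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    phi = 2 * np.pi * k / golden
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    names = [f"E{i + 1:02d}" for i in range(n_channels)]
    return MontageLayout(names, pos)
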