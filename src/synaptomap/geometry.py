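"""Physical voxel geometry and expansion-factor calibration.

Expansion microscopy physically enlarges the specimen by a linear factor
(~4x for the adapted MAP protocol), so every length measured on the image
grid lives on the *expanded* scale.  The conversion back to biological
(pre-expansion) scale is an exact division by the linear expansion factor::

    biological length = expanded length / expansion_factor

The expansion factor itself is calibrated from landmark length pairs
measured before and after expansion (e.g. DAPI overview images of the
same section).

Axis convention
---------------
Arrays are stored in ``(z, y, x)`` order with 0-based voxel indices.  A
voxel's physical position is its **center**: voxel ``i`` along an axis of
pitch ``d`` nm sits at ``(i + 0.5) * d`` nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

NM3_PER_UM3 = 1e9


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel pitch (expanded scale) plus the linear expansion factor.

    Parameters
    ----------
    voxel_size_zyx_nm:
        Physical voxel dimensions in nm along ``(z, y, x)``, expanded scale.
        The acquisition default is 190 x 50 x 50 nm (z, y, x).
    expansion_factor:
        Dimensionless linear expansion factor (> 0).  1.0 means the data
        are already on biological scale.
    """

    voxel_size_zyx_nm: tuple[float, float, float]
    expansion_factor: float = 1.0

    def __post_init__(self) -> None:
        size = tuple(float(v) for v in self.voxel_size_zyx_nm)
        if len(size) != 3 or any(v <= 0 for v in size):
            raise ValueError(f"voxel dimensions must be three positive lengths, got {size}")
        if not self.expansion_factor > 0:
            raise ValueError(f"expansion_factor must be > 0, got {self.expansion_factor}")
        object.__setattr__(self, "voxel_size_zyx_nm", size)
        object.__setattr__(self, "expansion_factor", float(self.expansion_factor))

    @classmethod
    def from_xyz(
        cls, voxel_size_xyz_nm: Sequence[float], expansion_factor: float = 1.0
    ) -> "VoxelGeometry":
        """Build from an ``(x, y, z)`` voxel size as written in imaging metadata."""
        x, y, z = voxel_size_xyz_nm
        return cls((float(z), float(y), float(x)), expansion_factor)

    @property
    def voxel_size_xyz_nm(self) -> tuple[float, float, float]:
        z, y, x = self.voxel_size_zyx_nm
        return (x, y, z)

    @property
    def voxel_volume_nm3(self) -> float:
        z, y, x = self.voxel_size_zyx_nm
        return z * y * x

    def voxel_centers_nm(self, indices: Iterable[Sequence[int]]) -> np.ndarray:
        """Physical centers (nm, expanded, zyx) of an ``(N, 3)`` set of voxel indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return (idx + 0.5) * np.asarray(self.voxel_size_zyx_nm)


def expansion_factor_from_landmarks(
    pairs: Iterable[tuple[float, float]],
) -> float:
    """Expansion factor from (pre-expansion, post-expansion) landmark length pairs.

    Returns the arithmetic mean of the per-pair ratios ``post / pre``.
    Both lengths of a pair must be positive and share units.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("at least one landmark length pair is required")
    ratios = []
    for pre, post in pairs:
        if pre <= 0 or post <= 0:
            raise ValueError(f"landmark lengths must be positive, got ({pre}, {post})")
        ratios.append(post / pre)
    return float(np.mean(ratios))


def to_biological(length_expanded_nm: float, geometry: VoxelGeometry) -> float:
    """Convert an expanded-scale length (nm) to biological scale (nm)."""
    if length_expanded_nm < 0:
        raise ValueError(f"length must be non-negative, got {length_expanded_nm}")
    return length_expanded_nm / geometry.expansion_factor


def to_expanded(length_biological_nm: float, geometry: VoxelGeometry) -> float:
    """Inverse of :func:`to_biological`."""
    if length_biological_nm < 0:
        raise ValueError(f"length must be non-negative, got {length_biological_nm}")
    return length_biological_nm * geometry.expansion_factor


def volume_biological_um3(n_voxels: int, geometry: VoxelGeometry) -> float:
    """Biological-scale volume (um^3) of ``n_voxels`` voxels.

    Divides the expanded voxel volume by the cube of the linear expansion
    factor; used as the denominator of density-per-tissue-volume measures.
    """
    if n_voxels < 0:
        raise ValueError(f"voxel count must be non-negative, got {n_voxels}")
    vol_nm3 = n_voxels * geometry.voxel_volume_nm3 / geometry.expansion_factor**3
    return vol_nm3 / NM3_PER_UM3
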