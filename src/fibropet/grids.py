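"""Voxel-grid container shared by the CT and PET sides of the pipeline.

A :class:`VolumeGrid` is a 3D scalar field with physical voxel spacing and an
explicit statement of what the numbers mean: Hounsfield units for CT,
activity concentration in kBq/mL for PET.  Keeping modality and units on the
object lets downstream operations refuse physically meaningless inputs
(e.g. a hypoxic-volume threshold applied to an FDG scan).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

#: Recognised modality -> value-unit pairs.
MODALITY_UNITS = {"CT": "HU", "PET": "kBq/mL"}


@dataclass
class VolumeGrid:
    """A 3D scalar volume with geometry and unit metadata.

    Parameters
    ----------
    data
        3D array of voxel values (stored as float32).
    spacing
        Voxel edge lengths in mm, one per axis; all strictly positive.
    modality
        ``"CT"`` or ``"PET"``.
    units
        ``"HU"`` for CT, ``"kBq/mL"`` for PET.
    orientation
        Axis convention tag; volumes written by this package are RAS.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    modality: str
    units: str = ""
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be three positive lengths, got {self.spacing}")
        if self.modality not in MODALITY_UNITS:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {sorted(MODALITY_UNITS)}")
        expected = MODALITY_UNITS[self.modality]
        if not self.units:
            self.units = expected
        elif self.units != expected:
            raise ValueError(f"{self.modality} volumes carry {expected}, got units={self.units!r}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL == 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """Same geometry and tags, new voxel values."""
        return replace(self, data=np.asarray(data, dtype=np.float32))

    def same_grid(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)
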