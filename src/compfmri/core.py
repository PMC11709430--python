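"""Shared in-memory containers for the compensation analysis.

The pipeline moves four kinds of objects between stages: behavioural
participant records, per-participant scan-by-voxel matrices, 3D statistic
maps, and boolean region-of-interest masks.  All voxel data live on a small
regular grid with a fixed affine; NIfTI round-trips go through
:mod:`nibabel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "ParticipantRecord",
    "VoxelDataset",
    "StatMap",
    "ROIMask",
    "RSFAMap",
    "default_affine",
]


def default_affine(voxel_size: float = 3.0) -> np.ndarray:
    """Isotropic affine used for all synthetic grids (mm units)."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


@dataclass
class ParticipantRecord:
    """One participant's identity, demographics and behavioural counts.

    ``performance`` follows the in-scanner fluid-intelligence score:
    correct minus incorrect trials, averaged over the hard and easy
    conditions.  Standardised covariates (``z_age``, ``z_performance``)
    are filled in at cohort level after any exclusions.
    """

    id: str
    age: float
    sex: str  # "F" | "M"
    hard_correct: int = 0
    hard_incorrect: int = 0
    easy_correct: int = 0
    easy_incorrect: int = 0
    z_age: float | None = None
    z_performance: float | None = None

    @property
    def performance(self) -> float:
        return (
            (self.hard_correct - self.hard_incorrect)
            + (self.easy_correct - self.easy_incorrect)
        ) / 2.0

    @property
    def n_trials(self) -> int:
        return (
            self.hard_correct
            + self.hard_incorrect
            + self.easy_correct
            + self.easy_incorrect
        )

    @property
    def proportion_correct(self) -> float:
        n = self.n_trials
        if n == 0:
            return np.nan
        return (self.hard_correct + self.easy_correct) / n


@dataclass
class VoxelDataset:
    """Scan x voxel matrix with the voxel coordinates that place each
    column on a 3D grid.

    Parameters
    ----------
    data:
        ``(n_scans, n_voxels)`` float array of BOLD values.
    coords:
        ``(n_voxels, 3)`` integer voxel indices into ``shape``.
    shape:
        3D grid shape.
    tr:
        Repetition time in seconds.
    """

    data: np.ndarray
    coords: np.ndarray
    shape: tuple[int, int, int]
    tr: float
    affine: np.ndarray = field(default_factory=default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        if self.data.ndim != 2 or self.coords.shape != (self.data.shape[1], 3):
            raise ValueError("data must be (n_scans, n_voxels) with matching coords")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def flat_indices(self) -> np.ndarray:
        """Raveled grid index of each voxel column (C order)."""
        return np.ravel_multi_index(self.coords.T, self.shape)

    def columns_in_mask(self, mask: np.ndarray) -> np.ndarray:
        """Column indices whose voxel falls inside a boolean 3D mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != tuple(self.shape):
            raise ValueError("mask shape does not match dataset grid")
        return np.nonzero(mask.ravel()[self.flat_indices])[0]

    def map_from_values(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a per-voxel vector back onto the 3D grid."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_voxels,):
            raise ValueError("one value per voxel required")
        grid = np.full(self.shape, fill, dtype=float)
        grid.ravel()[self.flat_indices] = values
        return grid

    def to_nifti(self) -> nib.Nifti1Image:
        vol = np.zeros(tuple(self.shape) + (self.n_scans,), dtype=np.float32)
        idx = tuple(self.coords.T)
        for t in range(self.n_scans):
            vol[idx + (t,)] = self.data[t]
        img = nib.Nifti1Image(vol, self.affine)
        img.header.set_zooms(img.header.get_zooms()[:3] + (self.tr,))
        return img

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image, mask: np.ndarray | None = None,
                   tr: float | None = None) -> "VoxelDataset":
        vol = np.asarray(img.get_fdata(), dtype=float)
        if vol.ndim != 4:
            raise ValueError("expected a 4D image")
        shape = vol.shape[:3]
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        coords = np.argwhere(mask)
        data = vol[mask].T  # (n_scans, n_voxels)
        if tr is None:
            zooms = img.header.get_zooms()
            tr = float(zooms[3]) if len(zooms) > 3 else 1.0
        return cls(data=data, coords=coords, shape=shape, tr=tr,
                   affine=np.asarray(img.affine))


@dataclass
class StatMap:
    """A 3D statistic map; NaN marks voxels outside the analysis mask."""

    values: np.ndarray
    kind: str = "coefficient"  # coefficient | t | p | tfce
    df: float | None = None
    affine: np.ndarray = field(default_factory=default_affine)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.values, dtype=np.float32),
                               self.affine)


@dataclass
class ROIMask:
    """Boolean 3D region-of-interest mask."""

    mask: np.ndarray
    label: str
    affine: np.ndarray = field(default_factory=default_affine)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.n_voxels == 0:
            raise ValueError(f"ROI {self.label!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.mask.astype(np.uint8), self.affine)


@dataclass
class RSFAMap:
    """Per-voxel resting-state fluctuation amplitude (always positive)."""

    values: np.ndarray
    affine: np.ndarray = field(default_factory=default_affine)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("RSFA values must be positive")

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.values, dtype=np.float32),
                               self.affine)


def records_to_frame(records: Sequence[ParticipantRecord]):
    """Tabulate participant records (used for TSV export and group models)."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append(
            dict(
                participant_id=r.id,
                age=r.age,
                sex=r.sex,
                hard_correct=r.hard_correct,
                hard_incorrect=r.hard_incorrect,
                easy_correct=r.easy_correct,
                easy_incorrect=r.easy_incorrect,
                performance=r.performance,
                z_age=r.z_age,
                z_performance=r.z_performance,
            )
        )
    return pd.DataFrame(rows)
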