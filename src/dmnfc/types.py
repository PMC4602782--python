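"""Shared spatial and cohort data types.

Conventions
-----------
Voxel indices are 0-based. The 4x4 affine maps homogeneous voxel indices
(i, j, k, 1) to MNI millimetre coordinates, as in the NIfTI-1 standard.
All seed and node placement is done in mm and mapped through the inverse
affine, so coordinates are independent of the grid.

Missing values in maps are encoded as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    MotionFileError,
    NonInvertibleAffineError,
    NotFourDimensionalError,
    UnknownGroupError,
    VolumeCountError,
)

#: Allowed cohort group labels. ``cirrhotic-undiagnosed`` marks patients whose
#: MHE / non-HE status has not yet been assigned from neuropsychological tests.
GROUPS = ("HC", "nonHE", "MHE", "cirrhotic-undiagnosed")

MAP_KINDS = ("r", "z", "t", "F", "p", "mean")


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition parameters of a BOLD series.

    Parameters
    ----------
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    n_volumes : int
        Number of volumes acquired (before any discarding).
    n_discard : int
        Number of initial volumes to drop for T1 equilibration.
    voxel_size_mm : tuple of float
        Voxel edge lengths in mm.
    """

    tr_seconds: float
    n_volumes: int
    n_discard: int = 0
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if self.n_volumes <= 0:
            raise ValueError(f"n_volumes must be positive, got {self.n_volumes}")
        if not 0 <= self.n_discard < self.n_volumes:
            raise ValueError(
                f"n_discard must satisfy 0 <= n_discard < n_volumes, "
                f"got {self.n_discard} with {self.n_volumes} volumes"
            )
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")

    @property
    def n_retained(self) -> int:
        return self.n_volumes - self.n_discard


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise NonInvertibleAffineError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise NonInvertibleAffineError("affine spatial block is singular")
    return affine


@dataclass
class BoldSeries:
    """A subject's 4-D BOLD lattice with affine and acquisition parameters."""

    data: np.ndarray
    affine: np.ndarray
    params: AcquisitionParams
    discarded: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise NotFourDimensionalError(
                f"BOLD data must be 4-D, got {self.data.ndim}-D"
            )
        self.affine = _check_affine(self.affine)
        expected = self.params.n_retained if self.discarded else self.params.n_volumes
        if self.data.shape[3] != expected:
            raise VolumeCountError(
                f"time axis has {self.data.shape[3]} volumes, expected {expected} "
                f"(discarded={self.discarded})"
            )

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class VolumeMap:
    """A 3-D scalar lattice with affine; ``kind`` tags its statistical meaning."""

    data: np.ndarray
    affine: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeMap data must be 3-D, got {self.data.ndim}-D")
        self.affine = _check_affine(self.affine)
        if self.kind not in MAP_KINDS:
            raise ValueError(f"kind must be one of {MAP_KINDS}, got {self.kind!r}")
        finite = self.data[np.isfinite(self.data)]
        if finite.size:
            if self.kind == "r" and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError("r map holds values outside [-1, 1]")
            if self.kind == "p" and (finite.min() < -1e-12 or finite.max() > 1 + 1e-9):
                raise ValueError("p map holds values outside [0, 1]")

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "VolumeMap":
        return VolumeMap(data=data, affine=self.affine, kind=kind or self.kind)


@dataclass
class BinaryMask:
    """A 3-D boolean lattice with affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask data must be 3-D, got {self.data.ndim}-D")
        self.affine = _check_affine(self.affine)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion parameters.

    ``translations_mm`` and ``rotations_deg`` each hold one row per acquired
    (pre-discard) volume, three columns each. Rotations are in degrees; radian
    input must be converted by the caller — units are never guessed.
    """

    translations_mm: np.ndarray
    rotations_deg: np.ndarray

    def __post_init__(self) -> None:
        self.translations_mm = np.atleast_2d(np.asarray(self.translations_mm, float))
        self.rotations_deg = np.atleast_2d(np.asarray(self.rotations_deg, float))
        if self.translations_mm.shape[1] != 3 or self.rotations_deg.shape[1] != 3:
            raise MotionFileError("motion trace needs 3 translation + 3 rotation columns")
        if self.translations_mm.shape[0] != self.rotations_deg.shape[0]:
            raise MotionFileError("translation and rotation row counts differ")

    @property
    def n_rows(self) -> int:
        return self.translations_mm.shape[0]

    @property
    def max_translation_mm(self) -> float:
        return float(np.abs(self.translations_mm).max())

    @property
    def max_rotation_deg(self) -> float:
        return float(np.abs(self.rotations_deg).max())

    def drop_initial(self, n: int) -> "MotionTrace":
        """Trace restricted to retained volumes, matching discard_initial."""
        if not 0 <= n < self.n_rows:
            raise VolumeCountError(f"cannot drop {n} of {self.n_rows} rows")
        return MotionTrace(self.translations_mm[n:], self.rotations_deg[n:])

    def as_array(self) -> np.ndarray:
        return np.hstack([self.translations_mm, self.rotations_deg])


@dataclass
class SubjectRecord:
    """One cohort member: demographics, group, neuropsych scores, file paths."""

    subject_id: str
    group: str
    age_years: float
    gender: str
    nct_a_seconds: float
    dst_score: int
    bold_path: str = ""
    motion_path: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise UnknownGroupError(
                f"group {self.group!r} for subject {self.subject_id!r} "
                f"not in {GROUPS}"
            )
        if self.gender not in ("M", "F"):
            raise ValueError(f"gender must be 'M' or 'F', got {self.gender!r}")
        if self.age_years <= 0:
            raise ValueError(f"age_years must be positive, got {self.age_years}")
        if self.nct_a_seconds <= 0:
            raise ValueError(f"nct_a_seconds must be positive, got {self.nct_a_seconds}")
        if self.dst_score < 0:
            raise ValueError(f"dst_score must be non-negative, got {self.dst_score}")

    def relabel(self, group: str) -> "SubjectRecord":
        return replace(self, group=group)


def voxel_to_mm(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map 0-based voxel indices (n x 3) to mm coordinates via the affine."""
    ijk = np.atleast_2d(ijk)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def mm_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Map mm coordinates (n x 3) to fractional 0-based voxel indices."""
    xyz = np.atleast_2d(xyz)
    inv = np.linalg.inv(affine)
    return xyz @ inv[:3, :3].T + inv[:3, 3]
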