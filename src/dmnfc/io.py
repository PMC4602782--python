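"""Readers and writers for the formats the pipeline touches.

NIfTI-1 volumes go through nibabel; manifests are delimited text tables read
with pandas; motion parameters are 6-column whitespace text (translations in
mm first, rotations in degrees — the common realignment-output convention).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    MissingColumnError,
    MotionFileError,
    NonNumericValueError,
    NotFourDimensionalError,
    UnknownGroupError,
)
from .types import (
    GROUPS,
    AcquisitionParams,
    BinaryMask,
    BoldSeries,
    MotionTrace,
    SubjectRecord,
    VolumeMap,
)

MANIFEST_COLUMNS = (
    "subject_id",
    "group",
    "age_years",
    "gender",
    "nct_a_seconds",
    "dst_score",
    "bold_path",
    "motion_path",
)


def _require_file(path: str | os.PathLike) -> Path:
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"no such file: {p}")
    return p


def read_bold(path: str | os.PathLike, n_discard: int = 0) -> BoldSeries:
    """Load a 4-D NIfTI-1 BOLD series.

    The repetition time is taken from the 4th header zoom (seconds). The
    ``n_discard`` bookkeeping field records how many initial volumes the
    preprocessing stage should drop; the file itself is returned untrimmed.
    """
    p = _require_file(path)
    img = nib.load(str(p))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise NotFourDimensionalError(f"{p} is not a 4-D series (ndim={data.ndim})")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    params = AcquisitionParams(
        tr_seconds=tr,
        n_volumes=data.shape[3],
        n_discard=n_discard,
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
    )
    return BoldSeries(data=data.astype(np.float64), affine=img.affine, params=params)


def write_bold(bold: BoldSeries, path: str | os.PathLike) -> None:
    """Write a BOLD series as float32 NIfTI-1, recording TR in the header."""
    p = Path(path)
    if not p.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {p.parent}")
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    zooms = bold.params.voxel_size_mm + (bold.params.tr_seconds,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(p))


def read_map(path: str | os.PathLike, kind: str) -> VolumeMap:
    """Load a 3-D NIfTI-1 statistical map of the given kind."""
    p = _require_file(path)
    img = nib.load(str(p))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{p} is not a 3-D map (ndim={data.ndim})")
    return VolumeMap(data=data.astype(np.float64), affine=img.affine, kind=kind)


def write_map(vmap: VolumeMap, path: str | os.PathLike) -> None:
    """Write a map as float32 NIfTI-1 (round-trips with read_map)."""
    p = Path(path)
    if not p.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {p.parent}")
    img = nib.Nifti1Image(vmap.data.astype(np.float32), vmap.affine)
    nib.save(img, str(p))


def read_mask(path: str | os.PathLike) -> BinaryMask:
    p = _require_file(path)
    img = nib.load(str(p))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{p} is not a 3-D mask (ndim={data.ndim})")
    return BinaryMask(data=data > 0.5, affine=img.affine)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    p = Path(path)
    if not p.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {p.parent}")
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(p))


def read_manifest(path: str | os.PathLike) -> list[SubjectRecord]:
    """Read a cohort manifest table (TSV or CSV, header row required)."""
    p = _require_file(path)
    sep = "\t" if p.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(p, sep=sep, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"manifest {p} lacks columns: {missing}")
    records = []
    for _, row in df.iterrows():
        group = str(row["group"])
        if group not in GROUPS:
            raise UnknownGroupError(
                f"manifest {p}: unknown group {group!r} for subject "
                f"{row['subject_id']!r}"
            )
        try:
            age = float(row["age_years"])
            nct = float(row["nct_a_seconds"])
            dst = int(float(row["dst_score"]))
        except (TypeError, ValueError) as exc:
            raise NonNumericValueError(
                f"manifest {p}: non-numeric score in row for subject "
                f"{row['subject_id']!r}: {exc}"
            ) from exc
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=group,
                age_years=age,
                gender=str(row["gender"]),
                nct_a_seconds=nct,
                dst_score=dst,
                bold_path=str(row["bold_path"]),
                motion_path=str(row["motion_path"]),
            )
        )
    return records


def write_manifest(records: Sequence[SubjectRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "age_years": r.age_years,
                "gender": r.gender,
                "nct_a_seconds": r.nct_a_seconds,
                "dst_score": r.dst_score,
                "bold_path": r.bold_path,
                "motion_path": r.motion_path,
            }
            for r in records
        ],
        columns=list(MANIFEST_COLUMNS),
    )
    p = Path(path)
    sep = "\t" if p.suffix.lower() in (".tsv", ".txt") else ","
    df.to_csv(p, sep=sep, index=False)


def read_motion(path: str | os.PathLike, n_volumes: int) -> MotionTrace:
    """Read a 6-column whitespace-delimited motion-parameter file.

    Columns 1-3 are translations in mm, 4-6 rotations in degrees. The row
    count must equal the pre-discard volume count.
    """
    p = _require_file(path)
    arr = np.loadtxt(str(p), ndmin=2)
    if arr.shape[1] != 6:
        raise MotionFileError(f"{p}: expected 6 columns, found {arr.shape[1]}")
    if arr.shape[0] != n_volumes:
        raise MotionFileError(
            f"{p}: expected {n_volumes} rows, found {arr.shape[0]}"
        )
    return MotionTrace(translations_mm=arr[:, :3], rotations_deg=arr[:, 3:])


def write_motion(trace: MotionTrace, path: str | os.PathLike) -> None:
    p = Path(path)
    if not p.parent.is_dir():
        raise FileNotFoundError(f"directory does not exist: {p.parent}")
    np.savetxt(str(p), trace.as_array(), fmt="%.6f")
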