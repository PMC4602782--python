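"""Seed-based DMN connectivity mapping and conjunction masking.

Per subject: the mean time series of each of three seed spheres (MPFC, PCC,
left lateral parietal) is correlated with every voxel, the r maps are
Fisher-transformed to z, and the three z maps are averaged into the
subject's DMN map. At the group level, a voxelwise one-sample t-test per
seed (Benjamini-Hochberg FDR-thresholded) yields three significance masks,
and a voxel joins the conjunction DMN mask when it is significant for at
least 2 of the 3 seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConstantSeedError,
    EmptySphereError,
    GridMismatchError,
    InsufficientSubjectsError,
)
from .types import BinaryMask, BoldSeries, VolumeMap, mm_to_voxel, voxel_to_mm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeedSpec:
    """A seed sphere: name, MNI-mm center, radius in mm.

    Radius 0 selects the single voxel containing the center.
    """

    name: str
    center_mni_mm: tuple[float, float, float]
    radius_mm: float = 6.0


def default_seeds() -> list[SeedSpec]:
    """The three canonical DMN seeds (MPFC, PCC, left lateral parietal)."""
    return [
        SeedSpec("MPFC", (-1.0, 47.0, -4.0), 6.0),
        SeedSpec("PCC", (-5.0, -49.0, 40.0), 6.0),
        SeedSpec("LP", (-45.0, -67.0, 36.0), 6.0),
    ]


def sphere_voxel_indices(
    shape: tuple[int, int, int], affine: np.ndarray, seed: SeedSpec
) -> np.ndarray:
    """Flat indices of voxels whose centers lie within radius_mm of the seed
    center (Euclidean distance in mm). Radius 0: the containing voxel."""
    center = np.asarray(seed.center_mni_mm, float)
    if seed.radius_mm == 0:
        cv = np.round(mm_to_voxel(affine, center)[0]).astype(int)
        if np.any(cv < 0) or np.any(cv >= np.asarray(shape)):
            raise EmptySphereError(
                f"seed {seed.name!r} center maps outside the grid at {cv}"
            )
        return np.array([np.ravel_multi_index(tuple(cv), shape)])
    ijk = np.indices(shape).reshape(3, -1).T
    mm = voxel_to_mm(affine, ijk.astype(float))
    d2 = ((mm - center) ** 2).sum(1)
    idx = np.flatnonzero(d2 <= seed.radius_mm**2)
    if idx.size == 0:
        raise EmptySphereError(f"seed {seed.name!r} sphere contains no voxel")
    return idx


def seed_timeseries(bold: BoldSeries, seed: SeedSpec) -> np.ndarray:
    """Mean time series over the seed sphere's voxels."""
    idx = sphere_voxel_indices(bold.shape3d, bold.affine, seed)
    data2d = bold.data.reshape(-1, bold.n_timepoints)
    return data2d[idx].mean(axis=0)


def correlation_map(bold: BoldSeries, seed_ts: np.ndarray) -> VolumeMap:
    """Voxelwise lag-zero Pearson correlation with the seed series.

    Zero-variance voxels map to NaN; a constant seed series raises.
    """
    seed_ts = np.asarray(seed_ts, float)
    if seed_ts.shape[0] != bold.n_timepoints:
        raise ValueError(
            f"seed series length {seed_ts.shape[0]} != volume count "
            f"{bold.n_timepoints}"
        )
    s = seed_ts - seed_ts.mean()
    s_norm = np.sqrt((s**2).sum())
    if s_norm == 0:
        raise ConstantSeedError("seed time series is constant")
    data2d = bold.data.reshape(-1, bold.n_timepoints)
    y = data2d - data2d.mean(axis=1, keepdims=True)
    y_norm = np.sqrt((y**2).sum(axis=1))
    # zero-variance detection must tolerate demeaning round-off on
    # constant series, which scales with the raw magnitude
    scale = np.sqrt((data2d.astype(float) ** 2).sum(axis=1))
    eps = np.finfo(data2d.dtype).eps if data2d.dtype.kind == "f" else 1e-16
    zero_var = y_norm <= 100.0 * eps * np.maximum(scale, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (y @ s) / (y_norm * s_norm)
    r[zero_var] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return VolumeMap(data=r.reshape(bold.shape3d), affine=bold.affine, kind="r")


def fisher_z(rmap: VolumeMap) -> VolumeMap:
    """Fisher r-to-z transform, z = atanh(r).

    |r| = 1 (infinite z) maps to NaN with a logged warning.
    """
    if rmap.kind != "r":
        raise ValueError(f"fisher_z expects an r map, got kind={rmap.kind!r}")
    r = rmap.data
    exact = np.isfinite(r) & (np.abs(r) >= 1.0)
    if exact.any():
        logger.warning(
            "fisher_z: %d voxels with |r| = 1 set to missing", int(exact.sum())
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.arctanh(r)
    z[exact] = np.nan
    return VolumeMap(data=z, affine=rmap.affine, kind="z")


def mean_seed_zmap(z_maps: list[VolumeMap]) -> VolumeMap:
    """Voxelwise arithmetic mean of per-seed z maps.

    A voxel missing (NaN) in any contributor is missing in the mean.
    """
    _check_same_grid([m.data.shape for m in z_maps])
    stack = np.stack([m.data for m in z_maps])
    return VolumeMap(data=stack.mean(axis=0), affine=z_maps[0].affine, kind="z")


def fdr_select(p_values: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up selection at level ``q``.

    Returns a boolean array marking the selected hypotheses (those with
    p <= p_(i*) for the largest i* with p_(i*) <= i*.q/m; empty if none).
    """
    p = np.asarray(p_values, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    if p.size == 0:
        return np.zeros(0, bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def seed_significance_mask(z_maps: list[VolumeMap], q: float) -> BinaryMask:
    """Group-level significance mask for one seed.

    Voxelwise one-sample t-test of z against 0 across subjects, two-sided p,
    BH-FDR selection at ``q``; surviving voxels additionally need positive
    mean z, since the mask encodes membership in a positively coupled
    network (global-signal regression shifts background correlations
    slightly negative, and a sign-blind mask would admit that bias).
    Voxels missing in any subject are excluded.
    """
    if len(z_maps) < 3:
        raise InsufficientSubjectsError(
            f"need at least 3 subjects, got {len(z_maps)}"
        )
    _check_same_grid([m.data.shape for m in z_maps])
    stack = np.stack([m.data.reshape(-1) for m in z_maps])
    valid = np.isfinite(stack).all(axis=0)
    mask = np.zeros(stack.shape[1], bool)
    if valid.any():
        t, p = stats.ttest_1samp(stack[:, valid], 0.0, axis=0)
        p = np.nan_to_num(p, nan=1.0)
        mask[valid] = fdr_select(p, q) & (t > 0)
    return BinaryMask(
        data=mask.reshape(z_maps[0].data.shape), affine=z_maps[0].affine
    )


def conjunction(masks: list[BinaryMask], min_agree: int = 2) -> BinaryMask:
    """Voxel true iff at least ``min_agree`` of the input masks are true."""
    _check_same_grid([m.data.shape for m in masks])
    count = np.sum([m.data.astype(int) for m in masks], axis=0)
    return BinaryMask(data=count >= min_agree, affine=masks[0].affine)


@dataclass
class ConjunctionResult:
    """Group conjunction outcome: per-seed masks, the combined DMN mask, and
    the per-subject mean z maps used downstream."""

    seed_masks: dict[str, BinaryMask]
    dmn_mask: BinaryMask
    subject_mean_zmaps: list[VolumeMap]


def subject_seed_zmaps(
    bold: BoldSeries, seeds: list[SeedSpec]
) -> dict[str, VolumeMap]:
    """z map for every seed of one (preprocessed) subject."""
    out = {}
    for seed in seeds:
        ts = seed_timeseries(bold, seed)
        out[seed.name] = fisher_z(correlation_map(bold, ts))
    return out


def build_conjunction(
    per_seed_zmaps: dict[str, list[VolumeMap]],
    subject_mean_zmaps: list[VolumeMap],
    q: float = 0.05,
) -> ConjunctionResult:
    """Build the 2-of-3 conjunction DMN mask from per-seed group z maps.

    ``per_seed_zmaps`` maps seed name -> z maps of the mask-defining group
    (conventionally the healthy controls, so patient data never shape the
    mask the groups are compared within).
    """
    seed_masks = {
        name: seed_significance_mask(maps, q) for name, maps in per_seed_zmaps.items()
    }
    dmn = conjunction(list(seed_masks.values()), min_agree=2)
    return ConjunctionResult(
        seed_masks=seed_masks, dmn_mask=dmn, subject_mean_zmaps=subject_mean_zmaps
    )


def _check_same_grid(shapes) -> None:
    shapes = list(shapes)
    if any(s != shapes[0] for s in shapes[1:]):
        raise GridMismatchError(f"inputs live on different grids: {shapes}")
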