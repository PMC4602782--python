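"""Voxelwise group inference with Monte-Carlo cluster-extent correction.

Three-group comparison of subject DMN z maps by covariate-adjusted ANOVA
(age and gender as covariates), post hoc pairwise t contrasts within the
significant ANOVA regions, cluster extraction under a configurable
connectivity rule, and a Monte-Carlo estimate (the AlphaSim procedure) of
the minimum cluster extent that controls family-wise error at a given
alpha for a given cluster-forming threshold and field smoothness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

from .errors import (
    DegenerateDataError,
    EmptyMaskError,
    EmptyRoiError,
    GridMismatchError,
    InsufficientSubjectsError,
    RankDeficientDesignError,
)
from .types import BinaryMask, VolumeMap, voxel_to_mm

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = factor * sigma


@dataclass
class DesignInfo:
    """Group labels and covariates for a cohort of subject maps."""

    groups: list[str]
    age_years: np.ndarray
    gender: np.ndarray  # coded 0/1 (0 = M, 1 = F)

    def __post_init__(self) -> None:
        self.age_years = np.asarray(self.age_years, float)
        self.gender = np.asarray(self.gender, float)
        n = len(self.groups)
        if self.age_years.shape != (n,) or self.gender.shape != (n,):
            raise ValueError("covariate lengths must match the number of subjects")
        if not (np.isfinite(self.age_years).all() and np.isfinite(self.gender).all()):
            raise ValueError("every subject needs complete covariates")

    def subset(self, keep: np.ndarray) -> "DesignInfo":
        keep = np.asarray(keep)
        return DesignInfo(
            groups=[g for g, k in zip(self.groups, keep) if k],
            age_years=self.age_years[keep],
            gender=self.gender[keep],
        )


@dataclass(frozen=True)
class Cluster:
    """A connected suprathreshold component of a statistical map."""

    voxel_indices: np.ndarray  # (k, 3) int array
    size: int
    peak_stat: float
    peak_mni_mm: tuple[float, float, float]

    def to_mask(self, shape: tuple[int, int, int], affine: np.ndarray) -> BinaryMask:
        data = np.zeros(shape, bool)
        data[tuple(self.voxel_indices.T)] = True
        return BinaryMask(data=data, affine=affine)


@dataclass
class ClusterCorrection:
    """Monte-Carlo cluster-extent correction settings and result.

    ``min_extent_k`` (filled by :func:`alphasim_min_extent`) is the smallest
    cluster size k with estimated P(max null cluster >= k) <= alpha.
    """

    cluster_forming_p: float = 0.01
    alpha: float = 0.05
    n_iterations: int = 1000
    connectivity: int = 26  # one of 6, 18, 26
    smoothness_fwhm_mm: tuple[float, float, float] = (8.0, 8.0, 8.0)
    min_extent_k: int | None = None

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if not 0 < self.cluster_forming_p < 1 or not 0 < self.alpha <= 1:
            raise ValueError("cluster_forming_p in (0,1) and alpha in (0,1] required")


def _connectivity_structure(rule: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[rule])


def _group_design(groups: list[str], design: DesignInfo) -> tuple[np.ndarray, np.ndarray]:
    """Full and reduced design matrices.

    Group is coded by treatment-contrast indicators with HC as reference
    (or the first label present), so post hoc signs read patient-minus-
    control. Full: [1, group dummies, age, gender]; reduced drops the
    group dummies.
    """
    levels = sorted(set(groups), key=lambda g: (g != "HC", g))
    n = len(groups)
    dummies = np.zeros((n, len(levels) - 1))
    for j, lev in enumerate(levels[1:]):
        dummies[:, j] = [1.0 if g == lev else 0.0 for g in groups]
    covs = np.column_stack([design.age_years, design.gender])
    full = np.column_stack([np.ones(n), dummies, covs])
    reduced = np.column_stack([np.ones(n), covs])
    return full, reduced


def _stack_maps(subject_maps: list[VolumeMap], mask: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    shapes = [m.data.shape for m in subject_maps] + [mask.data.shape]
    if any(s != shapes[0] for s in shapes[1:]):
        raise GridMismatchError(f"maps/mask on different grids: {set(shapes)}")
    flat_mask = mask.data.reshape(-1)
    Y = np.stack([m.data.reshape(-1)[flat_mask] for m in subject_maps])
    return Y, flat_mask


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares per column of Y for OLS on X."""
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    return (resid**2).sum(axis=0)


def voxelwise_anova(
    subject_maps: list[VolumeMap], design: DesignInfo, mask: BinaryMask
) -> tuple[VolumeMap, VolumeMap]:
    """Covariate-adjusted one-way ANOVA of the group factor, per masked voxel.

    F compares the full model [1, group dummies, age, gender] against the
    reduced model without the group dummies; p from F(g-1, n-p_full).
    Voxels with any missing subject value get NaN.
    """
    groups = design.groups
    levels = set(groups)
    if len(levels) < 2:
        raise InsufficientSubjectsError("need at least 2 groups")
    for lev in levels:
        if groups.count(lev) < 2:
            raise InsufficientSubjectsError(f"group {lev!r} has fewer than 2 subjects")
    X_full, X_red = _group_design(groups, design)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise RankDeficientDesignError("ANOVA design matrix is rank deficient")
    Y, flat_mask = _stack_maps(subject_maps, mask)
    n, p_full = X_full.shape
    df1 = X_full.shape[1] - X_red.shape[1]
    df2 = n - p_full
    if df2 <= 0:
        raise InsufficientSubjectsError("not enough subjects for the model df")
    valid = np.isfinite(Y).all(axis=0)
    F = np.full(Y.shape[1], np.nan)
    P = np.full(Y.shape[1], np.nan)
    if valid.any():
        Yv = Y[:, valid]
        rss_f = _rss(X_full, Yv)
        rss_r = _rss(X_red, Yv)
        # exact-fit voxels: both RSS at round-off scale relative to the data
        scale = n * np.maximum((Yv**2).mean(axis=0), 1e-30)
        exact = rss_f <= 1e-20 * scale
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((rss_r - rss_f) / df1) / (rss_f / df2)
        f = np.where(exact, np.where(rss_r <= 1e-20 * scale, 0.0, np.inf), f)
        f = np.maximum(f, 0.0)
        F[valid] = f
        P[valid] = stats.f.sf(f, df1, df2)
    shape = mask.data.shape
    f_map = np.full(int(np.prod(shape)), np.nan)
    p_map = np.full(int(np.prod(shape)), np.nan)
    f_map[flat_mask] = F
    p_map[flat_mask] = P
    affine = subject_maps[0].affine
    return (
        VolumeMap(f_map.reshape(shape), affine, "F"),
        VolumeMap(p_map.reshape(shape), affine, "p"),
    )


def posthoc_t(
    subject_maps: list[VolumeMap], design: DesignInfo, mask: BinaryMask
) -> tuple[VolumeMap, VolumeMap]:
    """Two-group contrast with covariates, per masked voxel.

    t is the group-indicator coefficient in [1, group, age, gender]; the
    indicator is 1 for the non-reference group (HC, else the
    lexicographically first label, is the reference), so positive t means
    higher values in the non-reference group. p is two-sided.
    """
    levels = set(design.groups)
    if len(levels) != 2:
        raise InsufficientSubjectsError(f"post hoc t needs exactly 2 groups, got {levels}")
    for lev in levels:
        if design.groups.count(lev) < 2:
            raise InsufficientSubjectsError(f"group {lev!r} has fewer than 2 subjects")
    X, _ = _group_design(design.groups, design)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientDesignError("post hoc design matrix is rank deficient")
    Y, flat_mask = _stack_maps(subject_maps, mask)
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise InsufficientSubjectsError("not enough subjects for the model df")
    XtX_inv = np.linalg.inv(X.T @ X)
    c = XtX_inv[1, 1]  # group indicator is column 1
    valid = np.isfinite(Y).all(axis=0)
    T = np.full(Y.shape[1], np.nan)
    P = np.full(Y.shape[1], np.nan)
    if valid.any():
        Yv = Y[:, valid]
        beta = XtX_inv @ (X.T @ Yv)
        resid = Yv - X @ beta
        sigma2 = (resid**2).sum(axis=0) / df
        scale = np.maximum((Yv**2).mean(axis=0), 1e-30)
        exact = sigma2 <= 1e-20 * scale  # model fits to round-off
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[1] / np.sqrt(sigma2 * c)
            t = np.where(
                exact,
                np.where(
                    np.abs(beta[1]) <= 1e-8 * np.sqrt(scale),
                    0.0,
                    np.sign(beta[1]) * np.inf,
                ),
                t,
            )
        T[valid] = t
        P[valid] = 2.0 * stats.t.sf(np.abs(t), df)
    shape = mask.data.shape
    t_map = np.full(int(np.prod(shape)), np.nan)
    p_map = np.full(int(np.prod(shape)), np.nan)
    t_map[flat_mask] = T
    p_map[flat_mask] = P
    affine = subject_maps[0].affine
    return (
        VolumeMap(t_map.reshape(shape), affine, "t"),
        VolumeMap(p_map.reshape(shape), affine, "p"),
    )


def estimate_smoothness(
    residual_maps: list[VolumeMap],
    mask: BinaryMask,
    voxel_size_mm: tuple[float, float, float],
) -> tuple[float, float, float]:
    """Per-axis FWHM (mm) of the residual fields' spatial autocorrelation.

    Classical first-difference estimator: for a Gaussian autocorrelation
    field, adjacent-voxel correlation rho relates to the equivalent
    smoothing kernel by FWHM = d * sqrt(-2 ln 2 / ln rho), with
    rho = 1 - var(diff) / (2 var), estimated within the mask and pooled
    over maps. Estimates are clipped below at the voxel size.
    """
    if len(residual_maps) < 2:
        raise InsufficientSubjectsError("need at least 2 residual maps")
    if not mask.data.any():
        raise EmptyMaskError("smoothness mask is empty")
    stack = np.stack([m.data for m in residual_maps])  # maps x X x Y x Z
    m = mask.data
    vals = stack[:, m]
    var = vals[np.isfinite(vals)].var()
    if var <= 0:
        raise DegenerateDataError("residual maps are constant; smoothness undefined")
    fwhm = []
    for axis, d in zip(range(3), voxel_size_mm):
        diff = np.diff(stack, axis=axis + 1)
        pair = m.take(range(0, m.shape[axis] - 1), axis=axis) & m.take(
            range(1, m.shape[axis]), axis=axis
        )
        dv = diff[:, pair]
        dv = dv[np.isfinite(dv)]
        if dv.size == 0:
            fwhm.append(float(d))
            continue
        rho = 1.0 - dv.var() / (2.0 * var)
        if rho <= 0 or rho >= 1:
            fwhm.append(float(d))
            continue
        est = d * np.sqrt(-2.0 * np.log(2.0) / np.log(rho))
        fwhm.append(float(max(est, d)))
    return tuple(fwhm)  # type: ignore[return-value]


def alphasim_min_extent(
    correction: ClusterCorrection, mask: BinaryMask, rng_seed: int
) -> ClusterCorrection:
    """Monte-Carlo minimum cluster extent controlling family-wise error.

    Each iteration draws a Gaussian white field on the grid, smooths it to
    the configured FWHM, standardizes within the mask, thresholds two-sided
    at the cluster-forming p, and records the maximum cluster size under
    the connectivity rule. ``min_extent_k`` is the smallest k for which the
    fraction of iterations whose maximum cluster reaches k is <= alpha.
    """
    if correction.n_iterations < 100:
        raise ValueError("n_iterations must be at least 100")
    if not mask.data.any():
        raise EmptyMaskError("correction mask is empty")
    voxel = _voxel_sizes_from_affine(mask.affine)
    sigma = [f / FWHM_FACTOR / v for f, v in zip(correction.smoothness_fwhm_mm, voxel)]
    if any(f < v for f, v in zip(correction.smoothness_fwhm_mm, voxel)):
        raise ValueError(
            f"smoothness FWHM {correction.smoothness_fwhm_mm} below voxel size {voxel}"
        )
    rng = np.random.default_rng(rng_seed)
    structure = _connectivity_structure(correction.connectivity)
    zcrit = stats.norm.isf(correction.cluster_forming_p / 2.0)
    m = mask.data
    shape = m.shape
    max_sizes = np.zeros(correction.n_iterations, int)
    for it in range(correction.n_iterations):
        fieldv = rng.standard_normal(shape)
        fieldv = ndimage.gaussian_filter(fieldv, sigma=sigma, mode="constant")
        v = fieldv[m]
        fieldv = (fieldv - v.mean()) / v.std()
        supra = (np.abs(fieldv) > zcrit) & m
        labels, n_lab = ndimage.label(supra, structure=structure)
        if n_lab:
            sizes = np.bincount(labels.reshape(-1))[1:]
            max_sizes[it] = sizes.max()
    # smallest k with P(max >= k) <= alpha
    ks = np.arange(1, max_sizes.max() + 2)
    exceed = (max_sizes[None, :] >= ks[:, None]).mean(axis=1)
    k_min = int(ks[np.argmax(exceed <= correction.alpha)])
    return replace(correction, min_extent_k=k_min)


def _voxel_sizes_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, j])) for j in range(3))


def extract_clusters(
    stat_map: VolumeMap,
    p_map: VolumeMap,
    forming_p: float,
    min_extent_k: int,
    connectivity: int = 26,
) -> list[Cluster]:
    """Connected components of {p < forming_p} with size >= min_extent_k,
    sorted by size descending. Peak is the voxel maximizing |stat|."""
    if stat_map.data.shape != p_map.data.shape:
        raise GridMismatchError("stat and p maps live on different grids")
    supra = np.isfinite(p_map.data) & (p_map.data < forming_p)
    labels, n_lab = ndimage.label(supra, structure=_connectivity_structure(connectivity))
    clusters: list[Cluster] = []
    for lab in range(1, n_lab + 1):
        idx = np.argwhere(labels == lab)
        if idx.shape[0] < min_extent_k:
            continue
        vals = stat_map.data[tuple(idx.T)]
        vals = np.where(np.isfinite(vals), vals, 0.0)
        peak = idx[np.argmax(np.abs(vals))]
        peak_mm = voxel_to_mm(stat_map.affine, peak.astype(float))[0]
        clusters.append(
            Cluster(
                voxel_indices=idx,
                size=int(idx.shape[0]),
                peak_stat=float(stat_map.data[tuple(peak)]),
                peak_mni_mm=tuple(float(x) for x in peak_mm),
            )
        )
    clusters.sort(key=lambda c: c.size, reverse=True)
    return clusters


def roi_mean(subject_map: VolumeMap, roi: Cluster | BinaryMask) -> float:
    """Mean of the subject's map over the ROI, ignoring missing voxels."""
    if isinstance(roi, Cluster):
        vals = subject_map.data[tuple(roi.voxel_indices.T)]
    else:
        if roi.data.shape != subject_map.data.shape:
            raise GridMismatchError("ROI and map live on different grids")
        vals = subject_map.data[roi.data]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise EmptyRoiError("ROI is empty after missing-value removal")
    return float(vals.mean())
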