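"""Per-subject preprocessing chain for resting-state BOLD data.

Stage order is discard -> motion screen -> spatial smoothing -> nuisance
regression -> band-pass filtering. Slice-timing correction, realignment
estimation and spatial normalization are out of scope: inputs are assumed
to sit in a common space, with realignment motion parameters supplied as
text files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from .errors import (
    AlreadyDiscardedError,
    BandSpecError,
    EmptyMaskError,
    RankDeficientDesignError,
    VolumeCountError,
)
from .types import AcquisitionParams, BinaryMask, BoldSeries, MotionTrace

#: FWHM of a Gaussian = 2 * sqrt(2 ln 2) * sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class NuisanceSet:
    """Which nuisance regressors to remove (all on by default)."""

    motion: bool = True
    csf: bool = True
    wm: bool = True
    global_signal: bool = True


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    Defaults: drop 10 equilibration volumes, exclude subjects moving more
    than 1.0 mm translation or 1.0 degree rotation (strict inequality:
    boundary-equal subjects are retained), smooth with an 8 mm FWHM
    isotropic Gaussian, regress 6 motion parameters plus CSF / WM / global
    mean signals, and band-pass to 0.01-0.08 Hz.
    """

    n_discard: int = 10
    translation_limit_mm: float = 1.0
    rotation_limit_deg: float = 1.0
    smooth_fwhm_mm: float = 8.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    nuisance: NuisanceSet = field(default_factory=NuisanceSet)

    def validate(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not 0 < self.band_low_hz < self.band_high_hz < nyquist:
            raise BandSpecError(
                f"band ({self.band_low_hz}, {self.band_high_hz}) Hz must satisfy "
                f"0 < low < high < Nyquist ({nyquist} Hz at TR {tr_seconds} s)"
            )


@dataclass(frozen=True)
class MotionVerdict:
    """Outcome of motion screening, carrying the offending maxima."""

    excluded: bool
    max_translation_mm: float
    max_rotation_deg: float

    @property
    def reason(self) -> str:
        if not self.excluded:
            return ""
        return (
            f"max translation {self.max_translation_mm:.3f} mm, "
            f"max rotation {self.max_rotation_deg:.3f} deg"
        )


def discard_initial(bold: BoldSeries, n: int) -> BoldSeries:
    """Drop the first ``n`` volumes (T1 equilibration).

    ``n = 0`` returns an identical series. A series already flagged as
    discarded cannot be discarded again.
    """
    if n < 0:
        raise VolumeCountError(f"n must be non-negative, got {n}")
    if n == 0:
        return replace(bold, data=bold.data.copy())
    if bold.discarded:
        raise AlreadyDiscardedError("initial volumes were already discarded")
    if n >= bold.n_timepoints:
        raise VolumeCountError(
            f"cannot discard {n} of {bold.n_timepoints} volumes"
        )
    params = AcquisitionParams(
        tr_seconds=bold.params.tr_seconds,
        n_volumes=bold.params.n_volumes,
        n_discard=n,
        voxel_size_mm=bold.params.voxel_size_mm,
    )
    return BoldSeries(
        data=bold.data[..., n:], affine=bold.affine, params=params, discarded=True
    )


def screen_motion(trace: MotionTrace, config: PreprocessConfig) -> MotionVerdict:
    """Exclusion verdict: excluded iff any |translation| exceeds the mm limit
    or any |rotation| exceeds the degree limit (strictly)."""
    mt = trace.max_translation_mm
    mr = trace.max_rotation_deg
    excluded = mt > config.translation_limit_mm or mr > config.rotation_limit_deg
    return MotionVerdict(excluded=excluded, max_translation_mm=mt, max_rotation_deg=mr)


def smooth(bold: BoldSeries, fwhm_mm: float) -> BoldSeries:
    """Convolve each volume with an isotropic Gaussian of the given FWHM.

    The FWHM is specified in mm and converted to voxels per axis; the kernel
    is unit-mass, so constant volumes are unchanged and total intensity of
    interior-supported signal is conserved.
    """
    if fwhm_mm <= 0:
        raise ValueError(f"fwhm_mm must be positive, got {fwhm_mm}")
    sigma_vox = [
        fwhm_mm * FWHM_TO_SIGMA / v for v in bold.params.voxel_size_mm
    ]
    out = ndimage.gaussian_filter(
        bold.data,
        sigma=sigma_vox + [0.0],
        mode="constant",
        cval=0.0,
        truncate=4.0,
    )
    return replace(bold, data=out)


def _mask_mean_series(data2d: np.ndarray, mask: BinaryMask, shape3d) -> np.ndarray:
    flat = mask.data.reshape(-1)
    if mask.data.shape != tuple(shape3d):
        raise ValueError(
            f"mask shape {mask.data.shape} does not match grid {tuple(shape3d)}"
        )
    if not flat.any():
        raise EmptyMaskError("nuisance mask selects no voxels")
    return data2d[flat].mean(axis=0)


def nuisance_design(
    bold: BoldSeries,
    trace: MotionTrace,
    csf_mask: BinaryMask | None,
    wm_mask: BinaryMask | None,
    brain_mask: BinaryMask | None,
    config: PreprocessConfig,
) -> tuple[np.ndarray, list[str]]:
    """Build the nuisance design matrix [intercept | regressors] and its
    column names. The motion trace must already be trimmed to the retained
    volumes."""
    n_t = bold.n_timepoints
    if trace.n_rows != n_t:
        raise VolumeCountError(
            f"motion trace has {trace.n_rows} rows but series has {n_t} volumes; "
            "trim the trace to the retained volumes first"
        )
    data2d = bold.data.reshape(-1, n_t)
    cols = [np.ones(n_t)]
    names = ["intercept"]
    if config.nuisance.motion:
        motion = trace.as_array()
        for i, nm in enumerate(
            ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        ):
            cols.append(motion[:, i])
            names.append(nm)
    if config.nuisance.csf:
        if csf_mask is None:
            raise ValueError("CSF regression requested but no CSF mask supplied")
        cols.append(_mask_mean_series(data2d, csf_mask, bold.shape3d))
        names.append("csf_mean")
    if config.nuisance.wm:
        if wm_mask is None:
            raise ValueError("WM regression requested but no WM mask supplied")
        cols.append(_mask_mean_series(data2d, wm_mask, bold.shape3d))
        names.append("wm_mean")
    if config.nuisance.global_signal:
        if brain_mask is None:
            raise ValueError("global regression requested but no brain mask supplied")
        cols.append(_mask_mean_series(data2d, brain_mask, bold.shape3d))
        names.append("global_mean")
    X = np.column_stack(cols)
    return X, names


def regress_nuisance(
    bold: BoldSeries,
    trace: MotionTrace,
    csf_mask: BinaryMask | None,
    wm_mask: BinaryMask | None,
    brain_mask: BinaryMask | None,
    config: PreprocessConfig,
) -> BoldSeries:
    """Voxelwise OLS removal of nuisance variance; returns the residuals.

    The design holds an intercept, the six motion parameters, and the mean
    CSF / WM / whole-brain series (per the configured nuisance set).
    Residuals are orthogonal to every regressor. A rank-deficient design
    raises, naming the collinear columns.
    """
    X, names = nuisance_design(bold, trace, csf_mask, wm_mask, brain_mask, config)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full-ish rank
        bad = []
        for j in range(1, X.shape[1]):
            Xj = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xj) == rank:
                bad.append(names[j])
        raise RankDeficientDesignError(
            f"nuisance design is rank deficient (rank {rank} of {X.shape[1]}); "
            f"collinear columns: {bad}",
            columns=tuple(bad),
        )
    Y = bold.data.reshape(-1, bold.n_timepoints).T  # time x voxels
    Q, _ = np.linalg.qr(X)
    Q = Q.astype(Y.dtype, copy=False)
    resid = Y - Q @ (Q.T @ Y)
    return replace(bold, data=resid.T.reshape(bold.data.shape))


def bandpass_array(
    x: np.ndarray, tr_seconds: float, low_hz: float, high_hz: float,
    transition_hz: float = 0.005,
) -> np.ndarray:
    """Zero-phase band-pass along the last axis.

    Implemented as a real-FFT frequency-domain window: unit gain inside
    [low, high], zero outside, raised-cosine transitions of width
    ``transition_hz`` centered on the band edges. The DC bin is always
    zeroed, so constant series map to zero. Frequency-domain real windowing
    introduces no phase shift, which matters because phase shifts would
    bias lag-zero correlations.
    """
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not 0 < low_hz < high_hz < nyquist:
        raise BandSpecError(
            f"band ({low_hz}, {high_hz}) Hz outside (0, Nyquist={nyquist} Hz)"
        )
    n_t = x.shape[-1]
    freqs = np.fft.rfftfreq(n_t, d=tr_seconds)
    gain = np.zeros_like(freqs)
    half = transition_hz / 2.0
    gain[(freqs >= low_hz + half) & (freqs <= high_hz - half)] = 1.0
    lo_band = (freqs > low_hz - half) & (freqs < low_hz + half)
    gain[lo_band] = 0.5 * (1 + np.sin(np.pi * (freqs[lo_band] - low_hz) / transition_hz))
    hi_band = (freqs > high_hz - half) & (freqs < high_hz + half)
    gain[hi_band] = 0.5 * (1 - np.sin(np.pi * (freqs[hi_band] - high_hz) / transition_hz))
    gain[0] = 0.0
    spec = sfft.rfft(x, axis=-1)
    spec *= gain.astype(spec.real.dtype)
    return sfft.irfft(spec, n=n_t, axis=-1)


def bandpass(bold: BoldSeries, low_hz: float, high_hz: float) -> BoldSeries:
    """Band-pass every voxel time series (see :func:`bandpass_array`)."""
    out = bandpass_array(bold.data, bold.params.tr_seconds, low_hz, high_hz)
    return replace(bold, data=out)


def preprocess_subject(
    bold: BoldSeries,
    trace: MotionTrace,
    csf_mask: BinaryMask | None,
    wm_mask: BinaryMask | None,
    brain_mask: BinaryMask | None,
    config: PreprocessConfig,
) -> tuple[BoldSeries | None, MotionVerdict]:
    """Run the full chain on one subject.

    Returns ``(processed, verdict)``; ``processed`` is None when the subject
    is excluded for motion.
    """
    config.validate(bold.params.tr_seconds)
    verdict = screen_motion(trace, config)
    if verdict.excluded:
        return None, verdict
    out = discard_initial(bold, config.n_discard)
    trimmed = trace.drop_initial(config.n_discard) if config.n_discard else trace
    out = smooth(out, config.smooth_fwhm_mm)
    out = regress_nuisance(out, trimmed, csf_mask, wm_mask, brain_mask, config)
    out = bandpass(out, config.band_low_hz, config.band_high_hz)
    return out, verdict
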