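"""Synthetic resting-state cohort with planted DMN connectivity.

The generator emulates the statistical structure of a three-group
resting-state fMRI study of cirrhosis: healthy controls (HC), cirrhotic
patients without hepatic encephalopathy (nonHE), and minimal hepatic
encephalopathy (MHE) patients, with inter-node DMN coupling decreasing
across that ordering.

Signal model, per subject
-------------------------
One latent network signal ``n(t)`` is drawn as a band-limited (0.01-0.08 Hz)
Gaussian process. Every voxel inside a DMN node sphere receives

    sqrt(rho) * n(t) + sqrt(1 - rho) * u_v(t)

where ``u_v`` is a voxel-unique band-limited process and ``rho`` is the
subject's planted inter-node correlation. Band-limited construction matters:
the planted correlation survives the pipeline's own 0.01-0.08 Hz band-pass
filter unchanged. On top of that every voxel receives white Gaussian noise,
a random linear drift, a shared global nuisance signal, motion-coupled
artifacts, and (inside small CSF/WM surrogate boxes) tissue-specific
nuisance signals. Non-node voxels carry noise and nuisance only.

Neuropsychological scores are linearly coupled to the planted connectivity:
number-connection-test-A time decreases with connectivity (longer time =
worse performance) and digit-symbol-test score increases with it.

Everything is deterministic given ``(master_seed, subject_seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .types import (
    AcquisitionParams,
    BinaryMask,
    BoldSeries,
    MotionTrace,
    SubjectRecord,
    VolumeMap,
    voxel_to_mm,
)

SIM_GROUPS = ("HC", "nonHE", "MHE")


@dataclass(frozen=True)
class NodeSpec:
    """A spherical DMN node: name, MNI-mm center, radius in mm."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float


def default_node_specs() -> list[NodeSpec]:
    """Six DMN node spheres.

    The first three sit at the classic seed coordinates (MPFC, PCC, left
    lateral parietal); the remainder are surrogates for left superior
    frontal gyrus and bilateral middle temporal gyri, the regions where
    group differences are expected to surface.
    """
    return [
        NodeSpec("MPFC", (-1.0, 47.0, -4.0), 6.0),
        NodeSpec("PCC", (-5.0, -49.0, 40.0), 6.0),
        NodeSpec("LP_L", (-45.0, -67.0, 36.0), 6.0),
        NodeSpec("SFG_L", (-16.0, 42.0, 34.0), 6.0),
        NodeSpec("MTG_L", (-48.0, -35.0, -6.0), 6.0),
        NodeSpec("MTG_R", (48.0, -35.0, -6.0), 6.0),
    ]


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    Defaults emulate the acquisition of the emulated study design: 250
    volumes at TR = 2 s of which the first 10 are discarded, 3 mm isotropic
    voxels, and inter-node correlations 0.60 / 0.45 / 0.30 for HC / nonHE /
    MHE. The grid is desk-scale (40 x 46 x 26 voxels) rather than a full
    MNI brain so a cohort simulates in minutes; it is exactly large enough
    to hold the default node spheres at their true MNI coordinates.
    """

    n_per_group: tuple[int, int, int] = (20, 20, 20)  # HC, nonHE, MHE
    grid_shape: tuple[int, int, int] = (40, 46, 26)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    acquisition: AcquisitionParams = field(
        default_factory=lambda: AcquisitionParams(
            tr_seconds=2.0, n_volumes=250, n_discard=10
        )
    )
    node_specs: list[NodeSpec] = field(default_factory=default_node_specs)
    rho_by_group: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.60, "nonHE": 0.45, "MHE": 0.30}
    )
    rho_subject_sd: float = 0.04
    noise_sd: float = 0.5
    drift_amplitude: float = 0.3
    global_amplitude: float = 0.3
    motion_sd_mm: float = 0.05
    motion_coupling: float = 0.1
    neuropsych_coupling: float = 1.0
    band_hz: tuple[float, float] = (0.01, 0.08)
    baseline: float = 100.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if any(n <= 0 for n in self.n_per_group):
            raise ConfigError(f"n_per_group must be positive, got {self.n_per_group}")
        for g in SIM_GROUPS:
            if g not in self.rho_by_group:
                raise ConfigError(f"rho_by_group lacks group {g!r}")
            rho = self.rho_by_group[g]
            if not 0.0 <= rho < 1.0:
                raise ConfigError(f"rho for {g} must lie in [0, 1), got {rho}")
        if self.noise_sd < 0 or self.drift_amplitude < 0 or self.motion_sd_mm < 0:
            raise ConfigError("noise/drift/motion amplitudes must be non-negative")
        # every node sphere must fit inside the grid
        affine = self.affine()
        shape = np.asarray(self.grid_shape, float)
        vox = np.asarray(self.voxel_size_mm, float)
        inv = np.linalg.inv(affine)
        for node in self.node_specs:
            c = np.asarray(node.center_mm, float)
            cv = c @ inv[:3, :3].T + inv[:3, 3]
            rv = node.radius_mm / vox
            if np.any(cv - rv < -0.5) or np.any(cv + rv > shape - 0.5):
                raise ConfigError(
                    f"node {node.name!r} sphere does not fit inside the grid "
                    f"(center voxel {np.round(cv, 1)}, shape {self.grid_shape})"
                )

    def affine(self) -> np.ndarray:
        """Voxel-to-mm affine: positive-diagonal scaling, grid centered on
        the bounding box of the node spheres (grid-independent placement)."""
        centers = np.array([n.center_mm for n in self.node_specs], float)
        radii = np.array([n.radius_mm for n in self.node_specs], float)[:, None]
        bbox_center = ((centers - radii).min(0) + (centers + radii).max(0)) / 2.0
        vox = np.asarray(self.voxel_size_mm, float)
        shape = np.asarray(self.grid_shape, float)
        offset = bbox_center - vox * (shape - 1) / 2.0
        affine = np.eye(4)
        affine[:3, :3] = np.diag(vox)
        affine[:3, 3] = offset
        return affine


@dataclass(frozen=True)
class GroundTruthRow:
    """Planted truth for one subject; written next to the manifest but never
    consumed by the analysis pipeline itself."""

    subject_id: str
    group: str
    rho_planted: float


def _grid_mm(config: CohortConfig) -> np.ndarray:
    shape = config.grid_shape
    ijk = np.indices(shape).reshape(3, -1).T.astype(float)
    return voxel_to_mm(config.affine(), ijk).reshape(*shape, 3)


def node_voxel_indices(config: CohortConfig) -> dict[str, np.ndarray]:
    """Flat voxel indices of each node sphere (voxel centers within radius)."""
    mm = _grid_mm(config).reshape(-1, 3)
    out: dict[str, np.ndarray] = {}
    for node in config.node_specs:
        d2 = ((mm - np.asarray(node.center_mm)) ** 2).sum(1)
        out[node.name] = np.flatnonzero(d2 <= node.radius_mm**2)
    return out


def node_label_map(config: CohortConfig) -> VolumeMap:
    """Integer label volume: 0 background, i+1 for the i-th node."""
    labels = np.zeros(int(np.prod(config.grid_shape)))
    for i, (name, idx) in enumerate(node_voxel_indices(config).items()):
        labels[idx] = i + 1
    return VolumeMap(
        data=labels.reshape(config.grid_shape), affine=config.affine(), kind="mean"
    )


def tissue_masks(config: CohortConfig) -> dict[str, BinaryMask]:
    """Surrogate brain / CSF / WM label masks emitted by the generator.

    The brain mask covers the whole grid; CSF and WM are small corner boxes
    that carry tissue-specific nuisance signals and stay clear of the nodes.
    """
    shape = config.grid_shape
    affine = config.affine()
    brain = np.ones(shape, bool)
    csf = np.zeros(shape, bool)
    wm = np.zeros(shape, bool)
    b = max(2, min(shape) // 6)
    csf[1 : 1 + b, 1 : 1 + b, 1 : 1 + b] = True
    wm[-1 - b : -1, -1 - b : -1, -1 - b : -1] = True
    node_idx = np.concatenate(list(node_voxel_indices(config).values()))
    node_mask = np.zeros(int(np.prod(shape)), bool)
    node_mask[node_idx] = True
    node_mask = node_mask.reshape(shape)
    if (csf & node_mask).any() or (wm & node_mask).any():
        raise ConfigError("CSF/WM surrogate boxes overlap a node sphere")
    return {
        "brain": BinaryMask(brain, affine),
        "csf": BinaryMask(csf, affine),
        "wm": BinaryMask(wm, affine),
    }


def band_limited_signals(
    rng: np.random.Generator,
    n_series: int,
    n_t: int,
    tr_seconds: float,
    band_hz: tuple[float, float],
) -> np.ndarray:
    """Unit-variance Gaussian processes with power confined to ``band_hz``.

    Sampled in the Fourier domain: independent complex-Gaussian coefficients
    on the in-band bins, zero elsewhere, then inverse real FFT and per-series
    standardization to mean 0, variance 1.
    """
    freqs = np.fft.rfftfreq(n_t, d=tr_seconds)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        raise ConfigError(f"no FFT bin falls inside band {band_hz}")
    spec = np.zeros((n_series, freqs.size), complex)
    k = int(in_band.sum())
    spec[:, in_band] = rng.standard_normal((n_series, k)) + 1j * rng.standard_normal(
        (n_series, k)
    )
    x = np.fft.irfft(spec, n=n_t, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _subject_rng(config: CohortConfig, subject_seed: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.master_seed), int(subject_seed)])
    )


def simulate_subject(
    config: CohortConfig,
    group: str,
    subject_seed: int,
    subject_id: str | None = None,
) -> tuple[BoldSeries, MotionTrace, SubjectRecord, GroundTruthRow]:
    """Simulate one subject's BOLD series, motion trace, record and truth."""
    if group not in config.rho_by_group or group not in SIM_GROUPS:
        raise ConfigError(f"group {group!r} not configured (have {SIM_GROUPS})")
    rng = _subject_rng(config, subject_seed)
    sid = subject_id or f"sub{subject_seed:04d}"

    shape = config.grid_shape
    n_vox = int(np.prod(shape))
    n_t = config.acquisition.n_volumes
    tr = config.acquisition.tr_seconds

    rho = float(
        np.clip(
            config.rho_by_group[group] + config.rho_subject_sd * rng.standard_normal(),
            0.0,
            0.95,
        )
    )

    # --- signals -----------------------------------------------------------
    network = band_limited_signals(rng, 1, n_t, tr, config.band_hz)[0]
    node_idx = node_voxel_indices(config)
    all_node_idx = np.concatenate(list(node_idx.values()))
    all_node_idx = np.unique(all_node_idx)
    unique = band_limited_signals(rng, all_node_idx.size, n_t, tr, config.band_hz)
    node_signal = np.sqrt(rho) * network[None, :] + np.sqrt(1.0 - rho) * unique

    global_sig = band_limited_signals(rng, 3, n_t, tr, (0.005, 0.1))
    csf_sig, wm_sig = global_sig[1], global_sig[2]
    global_sig = global_sig[0]

    # --- motion ------------------------------------------------------------
    steps = rng.standard_normal((n_t, 6))
    walk = np.cumsum(steps, axis=0)
    walk -= walk.mean(axis=0)
    sd = walk.std(axis=0)
    sd[sd == 0] = 1.0
    walk /= sd
    trans = walk[:, :3] * config.motion_sd_mm
    rot = walk[:, 3:] * config.motion_sd_mm  # degrees, same small scale
    trace = MotionTrace(translations_mm=trans, rotations_deg=rot)

    # --- assemble voxel x time matrix (float32: halves memory traffic) -----
    data = config.noise_sd * rng.standard_normal((n_vox, n_t), dtype=np.float32)
    ramp = np.linspace(-0.5, 0.5, n_t)
    drift_coeff = config.drift_amplitude * rng.standard_normal(n_vox)
    data += drift_coeff[:, None] * ramp[None, :]
    data += config.global_amplitude * global_sig[None, :]
    if config.motion_coupling > 0:
        weights = config.motion_coupling * rng.standard_normal((n_vox, 6))
        data += weights @ walk.T
    masks = tissue_masks(config)
    data[masks["csf"].data.reshape(-1)] += csf_sig[None, :]
    data[masks["wm"].data.reshape(-1)] += wm_sig[None, :]
    data[all_node_idx] += node_signal
    data += config.baseline

    bold = BoldSeries(
        data=data.reshape(*shape, n_t),
        affine=config.affine(),
        params=config.acquisition,
    )

    # --- demographics and neuropsych ---------------------------------------
    age = float(np.clip(rng.normal(48.0, 10.0), 20.0, 75.0))
    gender = "M" if rng.random() < 0.75 else "F"
    k = config.neuropsych_coupling
    nct = float(np.clip(92.0 - 80.0 * k * rho + rng.normal(0.0, 8.0), 15.0, None))
    dst = int(np.clip(round(18.0 + 42.0 * k * rho + rng.normal(0.0, 4.0)), 0, None))
    record = SubjectRecord(
        subject_id=sid,
        group=group,
        age_years=round(age, 1),
        gender=gender,
        nct_a_seconds=round(nct, 1),
        dst_score=dst,
    )
    truth = GroundTruthRow(subject_id=sid, group=group, rho_planted=rho)
    return bold, trace, record, truth


def inject_motion_outlier(
    trace: MotionTrace, magnitude_mm: float, volume_index: int | None = None
) -> MotionTrace:
    """Return a copy with one volume's x-translation set to ``magnitude_mm``.

    ``magnitude_mm = 0`` returns the trace unchanged.
    """
    if magnitude_mm < 0:
        raise ValueError(f"magnitude_mm must be non-negative, got {magnitude_mm}")
    if magnitude_mm == 0:
        return MotionTrace(trace.translations_mm.copy(), trace.rotations_deg.copy())
    idx = trace.n_rows // 2 if volume_index is None else volume_index
    trans = trace.translations_mm.copy()
    trans[idx, 0] = magnitude_mm
    return MotionTrace(translations_mm=trans, rotations_deg=trace.rotations_deg.copy())


def simulate_cohort(config: CohortConfig, out_dir: str | Path) -> Path:
    """Write a full synthetic cohort under ``out_dir``; return the manifest path.

    Emits one BOLD NIfTI and one motion text file per subject, the cohort
    manifest, tissue masks, a node label volume, and the ground-truth table.
    """
    from . import io as dio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "bold").mkdir(exist_ok=True)
    (out / "motion").mkdir(exist_ok=True)

    records: list[SubjectRecord] = []
    truths: list[GroundTruthRow] = []
    seed = 0
    for group, n in zip(SIM_GROUPS, config.n_per_group):
        for i in range(n):
            sid = f"sub-{group}{i:03d}"
            bold, trace, record, truth = simulate_subject(
                config, group, subject_seed=seed, subject_id=sid
            )
            bold_path = out / "bold" / f"{sid}.nii.gz"
            motion_path = out / "motion" / f"{sid}.txt"
            dio.write_bold(bold, bold_path)
            dio.write_motion(trace, motion_path)
            record.bold_path = str(bold_path)
            record.motion_path = str(motion_path)
            records.append(record)
            truths.append(truth)
            seed += 1

    manifest_path = out / "manifest.tsv"
    dio.write_manifest(records, manifest_path)
    pd.DataFrame([t.__dict__ for t in truths]).to_csv(
        out / "ground_truth.tsv", sep="\t", index=False
    )
    masks = tissue_masks(config)
    for name, mask in masks.items():
        dio.write_mask(mask, out / f"mask_{name}.nii.gz")
    dio.write_map(node_label_map(config), out / "node_labels.nii.gz")
    return manifest_path
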