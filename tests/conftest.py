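"""Shared fixtures: compact synthetic cohorts sized for fast tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from dmnfc.connectivity import SeedSpec
from dmnfc.inference import ClusterCorrection
from dmnfc.pipeline import RunConfig, SubjectData, analyze_subjects
from dmnfc.simulate import CohortConfig, NodeSpec, simulate_subject, tissue_masks
from dmnfc.types import AcquisitionParams

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: four compact nodes that fit a 36 mm box (12^3 grid at 3 mm)
COMPACT_NODES = [
    NodeSpec("A", (-8.0, -8.0, 0.0), 4.5),
    NodeSpec("B", (8.0, -8.0, 0.0), 4.5),
    NodeSpec("C", (-8.0, 8.0, 0.0), 4.5),
    NodeSpec("D", (8.0, 8.0, 0.0), 4.5),
]


def compact_config(**overrides) -> CohortConfig:
    """Small-grid cohort config for fast simulation."""
    kwargs = dict(
        n_per_group=(4, 4, 4),
        grid_shape=(12, 12, 12),
        node_specs=list(COMPACT_NODES),
        master_seed=7,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def compact_seeds(config: CohortConfig, n: int = 3) -> list[SeedSpec]:
    return [
        SeedSpec(s.name, s.center_mm, s.radius_mm) for s in config.node_specs[:n]
    ]


def simulate_in_memory(config: CohortConfig) -> list[SubjectData]:
    subjects = []
    seed = 0
    for group, n in zip(("HC", "nonHE", "MHE"), config.n_per_group):
        for i in range(n):
            bold, trace, rec, _ = simulate_subject(
                config, group, subject_seed=seed, subject_id=f"sub-{group}{i:03d}"
            )
            subjects.append(SubjectData(record=rec, bold=bold, trace=trace))
            seed += 1
    return subjects


@pytest.fixture(scope="session")
def mini_cohort():
    """A planted 8-per-group cohort on a 14x14x12 grid, analyzed end to end."""
    config = compact_config(
        n_per_group=(8, 8, 8),
        grid_shape=(14, 14, 12),
        node_specs=[
            NodeSpec("A", (-10.0, -10.0, 0.0), 4.5),
            NodeSpec("B", (10.0, -10.0, 0.0), 4.5),
            NodeSpec("C", (-10.0, 10.0, 0.0), 4.5),
            NodeSpec("D", (10.0, 10.0, 0.0), 4.5),
        ],
    )
    subjects = simulate_in_memory(config)
    masks = tissue_masks(config)
    run_config = RunConfig(
        seeds=compact_seeds(config),
        correction=ClusterCorrection(n_iterations=500),
        master_seed=7,
    )
    result = analyze_subjects(
        subjects, masks["csf"], masks["wm"], masks["brain"], run_config
    )
    return {"config": config, "subjects": subjects, "result": result,
            "run_config": run_config, "masks": masks}


@pytest.fixture(scope="session")
def recovery_cohort():
    """The parameter-recovery cohort: default grid and effect sizes,
    20 subjects per group, fully analyzed. Shared across the tests that
    check recovery of the planted group structure."""
    config = CohortConfig(n_per_group=(20, 20, 20), master_seed=11)
    subjects = simulate_in_memory(config)
    masks = tissue_masks(config)
    run_config = RunConfig(
        correction=ClusterCorrection(n_iterations=1000), master_seed=11
    )
    result = analyze_subjects(
        subjects, masks["csf"], masks["wm"], masks["brain"], run_config
    )
    return {"config": config, "subjects": subjects, "result": result}


def tiny_bold(data: np.ndarray, tr: float = 2.0, voxel: float = 3.0):
    """Wrap a 4-D array as a BoldSeries with a simple positive-diagonal affine."""
    from dmnfc.types import BoldSeries

    affine = np.diag([voxel, voxel, voxel, 1.0])
    params = AcquisitionParams(
        tr_seconds=tr,
        n_volumes=data.shape[3],
        voxel_size_mm=(voxel, voxel, voxel),
    )
    return BoldSeries(data=np.asarray(data, float), affine=affine, params=params)
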