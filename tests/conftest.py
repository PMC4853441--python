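"""Shared fixtures: toy spaces and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fluencymap.cohort import BehaviorRecord, GridGeometry, LesionMap, assemble_cohort
from fluencymap.synthetic import SyntheticConfig, make_cohort, make_toy_space


@pytest.fixture(scope="session")
def toy_space():
    return make_toy_space()


@pytest.fixture(scope="session")
def default_cohort():
    """Study-scale synthetic cohort (n = 93) under the default conditions."""
    return make_cohort(seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort for plumbing tests: 16^3 grid, 20 subjects."""
    config = SyntheticConfig(
        dims=(16, 16, 16), n_subjects=20, lesion_volume_range=(20, 120)
    )
    return make_cohort(config, seed=3)


def tiny_grid(n: int = 8) -> GridGeometry:
    return GridGeometry(
        dims=(n, n, n), voxel_size=(1.0, 1.0, 1.0), affine=np.eye(4), space_label="toy"
    )


@pytest.fixture
def grid8():
    return tiny_grid(8)


def handmade_cohort(lesion_voxels: dict[str, list[tuple[int, int, int]]], grid=None, scores=None):
    """Build a cohort from explicit lesioned-voxel lists and optional scores."""
    grid = grid or tiny_grid(8)
    maps = []
    records = []
    for i, (sid, voxels) in enumerate(lesion_voxels.items()):
        arr = np.zeros(grid.dims, dtype=np.uint8)
        for v in voxels:
            arr[v] = 1
        maps.append(LesionMap(subject_id=sid, grid=grid, voxels=arr))
        raw = dict(scores[sid]) if scores else {}
        records.append(
            BehaviorRecord(
                subject_id=sid,
                age=50.0 + i,
                sex=i % 2,
                education=3 + (i % 3),
                raw_scores=raw,
            )
        )
    return assemble_cohort(maps, records)
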