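"""Shared fixtures: small layouts and rendered scenes reused across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import wellpat as wp
from wellpat.pipeline import simulate_scene
from wellpat.scene import Optics


@pytest.fixture(scope="session")
def small_layout() -> wp.ArrayLayout:
    """~175-well array, fast to render yet large enough for statistics."""
    return wp.build_layout(footprint_um=(1560.0, 1560.0))


@pytest.fixture(scope="session")
def tiny_layout() -> wp.ArrayLayout:
    """~23-well array for end-to-end smoke tests."""
    return wp.build_layout(footprint_um=(600.0, 600.0))


@pytest.fixture(scope="session")
def mda_scene(small_layout):
    """One stencil-seeded scene with default noise, plus its ground truth."""
    cond = wp.condition_defaults("MDA-MB-231", 100, True, seed=42)
    images, gt = simulate_scene(small_layout, cond, Optics(), seed=42)
    return images, gt


def make_ground_truth(layout, positions_um, dead=None, condition=None):
    """Ground-truth table from explicit positions (testing helper)."""
    positions_um = np.asarray(positions_um, dtype=float).reshape(-1, 2)
    n = len(positions_um)
    if dead is None:
        dead = np.zeros(n, dtype=bool)
    if condition is None:
        condition = wp.SeedingCondition(
            name="manual", density_cells_per_mL=1.0, poisson_lambda=1.0
        )
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x_um": positions_um[:, 0],
            "y_um": positions_um[:, 1],
            "well_id": np.zeros(n, dtype=int),
            "is_interior": np.zeros(n, dtype=bool),
            "is_dead": np.asarray(dead, dtype=bool),
        }
    )
    return wp.SceneGroundTruth(cells=cells, condition=condition, layout=layout)


def truth_detections(layout) -> wp.WellDetectionSet:
    """A detection set built from the true layout centres (all sampled)."""
    wells = pd.DataFrame(
        {
            "well_id": np.arange(layout.n_wells),
            "x_um": layout.well_centers[:, 0],
            "y_um": layout.well_centers[:, 1],
            "ncc_score": np.ones(layout.n_wells),
        }
    )
    return wp.WellDetectionSet(
        wells=wells, ncc_threshold=0.5, sampled_ids=np.arange(layout.n_wells)
    )
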