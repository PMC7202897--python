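"""Shared fixtures: rasterized reference shapes and small synthetic studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from morphoinvasion import condition_stats, motility, synthetic
from morphoinvasion.morphometry import profile_table


def raster_disk(radius: float, offset: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """(n, 2) pixel coordinates of a filled disk rasterized at pixel centers."""
    n = int(np.ceil(radius)) + 3
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    inside = (xx - offset[1]) ** 2 + (yy - offset[0]) ** 2 <= radius**2
    return np.column_stack(np.nonzero(inside))


def raster_ellipse(a: float, b: float, phi: float = 0.0) -> np.ndarray:
    """Filled ellipse with semi-axes a (x) and b (y), rotated by phi."""
    n = int(np.ceil(max(a, b))) + 3
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    u = np.cos(phi) * xx + np.sin(phi) * yy
    v = -np.sin(phi) * xx + np.cos(phi) * yy
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return np.column_stack(np.nonzero(inside))


def study_tables(specs) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(features, metrics, spheroid folds) tables for a list of specs."""
    study = synthetic.generate_study(specs)
    features = pd.concat(
        [
            profile_table(masks, cond, [f"{cond}_{i}" for i in range(len(masks))])
            for cond, masks in study.masks.items()
        ],
        ignore_index=True,
    )
    metrics = motility.metrics_table(study.trajectories)
    folds = motility.spheroid_table(study.spheroids)
    return features, metrics, folds


def summary_frame_for(specs) -> pd.DataFrame:
    features, metrics, folds = study_tables(specs)
    return condition_stats.summary_frame(
        condition_stats.summarize(features, metrics, folds)
    )


@pytest.fixture(scope="session")
def recovery_frame() -> pd.DataFrame:
    """Condition-level summary of the 8-condition recovery study, seed 0."""
    return summary_frame_for(synthetic.recovery_study_specs(0, n_cells=50))


@pytest.fixture(scope="session")
def demo_tables():
    """Cell-level tables of the 5-condition demo study at reduced size."""
    return study_tables(synthetic.default_study_specs(0, n_cells=40))
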