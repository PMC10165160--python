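import numpy as np
import pandas as pd
import pytest

from abtau.cohort import SurfaceGeometry, VertexOverlay
from abtau.synthetic import GeneratorConfig, build_grid_geometry, generate_cohort
from abtau.categorize import GROUPS


@pytest.fixture
def tiny_geometry():
    """Six gray vertices in two regions, one white and one meningeal source.

    Gray vertices sit on the x axis at z = 0; the white source is at the
    origin, the meningeal source 2 mm above it.
    """
    coords = np.array([
        [0.0, 0.0, 0.0],    # white source
        [0.0, 0.0, 2.0],    # meningeal source
        [2.0, 0.0, 0.0],    # gray, region 0
        [3.0, 0.0, 0.0],    # gray, region 0
        [4.0, 0.0, 0.0],    # gray, region 0
        [2.0, 2.0, 0.0],    # gray, region 1
        [3.0, 2.0, 0.0],    # gray, region 1
        [50.0, 50.0, 0.0],  # excluded
    ])
    tissue = np.array(["white", "meninges", "gray", "gray", "gray", "gray",
                       "gray", "excluded"])
    region = np.array([-1, -1, 0, 0, 0, 1, 1, -1])
    hemi = np.array(["-", "-", "L", "L", "L", "R", "R", "-"])
    table = pd.DataFrame({"name": ["entorhinal", "entorhinal"],
                          "hemisphere": ["L", "R"]},
                         index=pd.Index([0, 1], name="region_id"))
    return SurfaceGeometry(coordinates=coords, tissue=tissue, region=region,
                           hemisphere=hemi, region_table=table)


def overlay_on(geometry, values, subject_id="s0", modality="abeta"):
    return VertexOverlay(subject_id=subject_id, modality=modality,
                         values=np.asarray(values, dtype=float))


@pytest.fixture(scope="session")
def grid_geometry():
    """Smallest legal parcellated grid (34 rows x 4 columns)."""
    return build_grid_geometry(grid_shape=(34, 4))


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared by integration tests."""
    cfg = GeneratorConfig(seed=5, grid_shape=(34, 8), n_young_abeta=30,
                          n_young_tau=20,
                          n_per_group={g: 30 for g in GROUPS})
    return cfg, generate_cohort(cfg)
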