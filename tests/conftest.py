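import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import gakinetics as gk


@pytest.fixture(scope="session")
def disk_masks():
    """Concentric rasterized disks 0.8 -> 0.95 mm at 12 um pitch."""
    return gk.make_disk_pair((3.0, 3.0), 0.8, 0.15)


@pytest.fixture(scope="session")
def disk_results(disk_masks):
    """Full growth-model fit of the concentric-disk scene (6 um working grid)."""
    m1, m2 = disk_masks
    return gk.GrowthModel(m1, m2, (3.0, 3.0), 1.0).fit()


@pytest.fixture(scope="session")
def merge_results():
    """Full fit of the symmetric two-foci merging scene."""
    scene = gk.make_merging_scene()
    m1, m2 = scene.to_masks()
    return gk.GrowthModel(m1, m2, scene.fovea_mm, 1.0).fit()


@pytest.fixture(scope="session")
def two_circle_results():
    """Full fit of the rasterized two-circle scene (R_alpha = 0.8 mm)."""
    scene = gk.make_two_circle_scene(0.8)
    m1, m2 = scene.to_masks()
    return gk.GrowthModel(m1, m2, scene.fovea_mm, scene.dt_years).fit()


@pytest.fixture(scope="session")
def all_fixture_results(disk_results, merge_results, two_circle_results):
    """Every fitted scene, for structural-invariant sweeps."""
    return {
        "disk": disk_results,
        "merge": merge_results,
        "gridsweep": two_circle_results,
    }
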