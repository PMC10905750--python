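"""Shared fixtures: desk-scale synthetic organs and meshes.

Test organs use coarse voxels (0.2 um xy) and few cells so every stage
runs in seconds; the geometry and statistical structure match the
generator's full-scale defaults.
"""

import numpy as np
import pytest
import trimesh

from neuroshape import PipelineConfig, SynthConfig, generate_neuromast, run_pipeline

DESK_VOXEL = (0.4, 0.2, 0.2)


def desk_config(**kw) -> SynthConfig:
    base = dict(n_cells=16, organ_radius_um=16.0, voxel_size_um=DESK_VOXEL, seed=1)
    base.update(kw)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def ground_truth():
    """One deterministic 16-cell rosette with default noise."""
    return generate_neuromast(desk_config())


@pytest.fixture(scope="session")
def ground_truth_clean():
    """Zero-noise variant for segmentation-accuracy checks."""
    return generate_neuromast(desk_config(noise_sd=0.0, seed=3))


@pytest.fixture(scope="session")
def pipeline_result():
    """A full two-organ pipeline run shared by downstream tests."""
    cfg = PipelineConfig(synth=desk_config(), n_organs=2, k_neighbors=8, seed=1)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)


@pytest.fixture()
def unit_sphere():
    return trimesh.creation.icosphere(subdivisions=4)


@pytest.fixture()
def ellipsoid():
    m = trimesh.creation.icosphere(subdivisions=4)
    m.vertices = m.vertices * np.array([1.0, 0.8, 0.6])
    return m
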