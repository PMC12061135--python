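"""Shared fixtures: reduced-size phantom specs and a small analysed cohort.

All fixtures are generated programmatically at test time; sizes are scaled
down from the full defaults to keep the suite fast while exercising the
same code paths.
"""

from __future__ import annotations

import numpy as np
import pytest

import diatomht as d
from diatomht.tomio import records_to_frame


def make_tomogram(value: float, shape=(4, 4, 4), voxel_size=(0.1, 0.1, 0.2),
                  dtype=np.float64) -> d.Tomogram:
    """Uniform-RI tomogram helper; float64 so exact band-edge values survive."""
    return d.Tomogram(ri=np.full(shape, value, dtype=dtype), voxel_size=voxel_size)


@pytest.fixture(scope="session")
def default_config() -> d.SegmentationConfig:
    return d.SegmentationConfig()


@pytest.fixture(scope="session")
def small_spec() -> d.PhantomSpec:
    """A reduced cell (~95k voxels) that renders in a few ms."""
    return d.PhantomSpec(
        cell_radius=1.8,
        cell_length=6.0,
        frustule_thickness=0.35,
        chloroplast_lobe_radius=0.6,
        vacuole_radius=0.6,
        grid_shape=(28, 48, 72),
        noise_sd=0.002,
    )


@pytest.fixture(scope="session")
def clean_small_spec(small_spec) -> d.PhantomSpec:
    """Same geometry, no noise, no blur: segmentation recovers it exactly."""
    import dataclasses

    return dataclasses.replace(small_spec, noise_sd=0.0, axial_blur_sigma=0.0)


@pytest.fixture(scope="session")
def small_cohort_frame(small_spec):
    """Fully analysed 3-condition × 4-time × 6-cell phantom cohort."""
    cohort = d.CohortSpec(
        conditions=(("CTRL", 0.0, None), ("Cd-10", 10.0, "Cd"), ("Cd-25", 25.0, "Cd")),
        cells_per_group=6,
        seed=7,
    )
    records = [
        d.build_cell_record(tomo, d.segment_by_ri(tomo), annotations=ann)
        for tomo, _, ann in d.generate_cohort(cohort, small_spec)
    ]
    return records_to_frame(records)
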