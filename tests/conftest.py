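"""Shared fixtures: small, fast study configurations and rendered images."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pulpmorph.pipeline import StudyConfig
from pulpmorph.synthetic import place_cells, render_study_image, stage_defaults

settings.register_profile(
    "suite", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_config() -> StudyConfig:
    """A scaled-down synthetic study that runs in seconds."""
    return StudyConfig(
        seed=7,
        n_cases=2,
        images_per_case=2,
        cells_per_image=30,
        image_shape=(1024, 1024),
        sample_size=40,
    )


@pytest.fixture(scope="session")
def rendered_cap_image(tiny_config):
    """One rendered cap-stage image with its truth labels and records."""
    params = stage_defaults(cells_per_image=30)["cap"]
    rng = np.random.default_rng(11)
    records = place_cells(
        params,
        tiny_config.image_shape,
        tiny_config.calibration_um_per_px,
        rng,
        "capfix",
        "img01",
    )
    image, truth = render_study_image(
        records, params, tiny_config.image_shape, tiny_config.calibration_um_per_px, rng
    )
    return image, truth, records, params
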