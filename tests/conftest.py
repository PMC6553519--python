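"""Shared synthetic fixtures.

All fixtures are generated programmatically; movie-producing ones are
session-scoped because synthesis dominates test runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

from wedgemap.apd import default_rois
from wedgemap.pacing import dynamic_protocol
from wedgemap.preprocessing import (
    build_quality_mask,
    filter_movie,
    normalize,
    segment_beats,
)
from wedgemap.synthetic import (
    make_activation_field,
    make_apd_field,
    preset_movie,
    synthesize_movie,
)


def prepare(movie, spatial_sigma_mm=1.0, temporal_window_ms=5.0, filter_first=True):
    """filter -> normalize -> mask -> windows, returning all stages."""
    from wedgemap.pipeline import preprocess

    if not filter_first:
        spatial_sigma_mm = temporal_window_ms = 0.0
    return preprocess(movie, spatial_sigma_mm, temporal_window_ms)


@pytest.fixture(scope="session")
def homog_movie():
    """Noise-free homogeneous 300 ms movie, 2 beats at 1 Hz, 30x30 px."""
    site = (15, 15)
    act = make_activation_field((30, 30), 1.0, site, 50.0, 50.0, 0.0)
    apd = make_apd_field((30, 30), 300.0, 0.0)
    return synthesize_movie(
        act, apd,
        dynamic_protocol([1.0], beats_per_frequency=2, stimulus_site=site),
        noise_sd=0.0, seed=0,
    )


@pytest.fixture(scope="session")
def noisy_rtof_endo_movie():
    """rTOF endocardial preset with heterogeneity and 2% noise, 40x40 px."""
    site = (20, 20)
    return preset_movie(
        "rtof", "endocardium", grid_shape=(40, 40), noise_sd=0.02, seed=1,
        protocol=dynamic_protocol([1.0], beats_per_frequency=2, stimulus_site=site),
        stimulus_site=site,
    )


@pytest.fixture(scope="session")
def rtof_dynamic_movie():
    """rTOF epicardial preset paced at 1-2.5 Hz (10 beats each), 30x30 px."""
    site = (15, 15)
    return preset_movie(
        "rtof", "epicardium", grid_shape=(30, 30), noise_sd=0.02, seed=7,
        protocol=dynamic_protocol(
            [1.0, 1.5, 2.0, 2.5], beats_per_frequency=10, stimulus_site=site
        ),
        stimulus_site=site,
    )


@pytest.fixture(scope="session")
def sham_restitution_movie():
    """Noise-free homogeneous sham preset paced 1-5 Hz, 30x30 px."""
    site = (15, 15)
    return preset_movie(
        "sham", "epicardium", grid_shape=(30, 30), noise_sd=0.0,
        heterogeneity_sd_ms=0.0, seed=7,
        protocol=dynamic_protocol(
            [1.0, 2.0, 3.0, 4.0, 5.0], beats_per_frequency=8, stimulus_site=site
        ),
        stimulus_site=site,
    )


@pytest.fixture(scope="session")
def rois30():
    return default_rois((30, 30), 1.0)
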