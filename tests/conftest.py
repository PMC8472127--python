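"""Shared fixtures: small synthetic acquisitions generated at test time."""

import numpy as np
import pytest

from effiq.synthetic import BeamStopGridSpec, make_beam_stop_image, make_edge_image, make_flat_field


@pytest.fixture(scope="session")
def clean_edge():
    """Noise-free slanted edge (3 deg, Gaussian PSF 0.2 mm) plus its truth."""
    return make_edge_image(
        angle_deg=3.0, sigma_mm=0.2, pitch_mm=0.143, shape=(360, 360), noise_sd=0.0, seed=11
    )


@pytest.fixture(scope="session")
def white_flats():
    """Four linearized white-noise flat fields (mean 1000, sd 10, pitch 0.1 mm)."""
    out = [make_flat_field(1000.0, 10.0, 0.1, (560, 560), seed=100 + i) for i in range(4)]
    return [img for img, _ in out], out[0][1]


@pytest.fixture(scope="session")
def beam_stop_grid():
    return BeamStopGridSpec(n_rows=11, n_cols=11, pitch_mm=12.0, cylinder_diameter_mm=5.0)


@pytest.fixture(scope="session")
def beam_stop_case(beam_stop_grid):
    """Noise-free beam-stop image with scatter fraction truth 0.30."""
    img, truth = make_beam_stop_image(
        beam_stop_grid, primary_level=700.0, scatter_level=300.0, lead_transmission=0.0,
        noise_sd=0.0, pitch_mm=0.143, shape=(1024, 1024), seed=3,
    )
    return img, truth, beam_stop_grid


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)
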