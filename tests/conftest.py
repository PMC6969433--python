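"""Shared fixtures: small synthetic movies with known ground truth."""

import numpy as np
import pytest

from smdwell.simulate import (
    BleachModel,
    PopulationSpec,
    SimulationTruth,
    make_fibril_geometry,
    render_movie,
    simulate_event_list,
)


@pytest.fixture(scope="session")
def small_truth():
    """Sparse, high-SNR imaging conditions on a small field (fast to render)."""
    return SimulationTruth(
        populations=[PopulationSpec(0.8, 12.0), PopulationSpec(0.2, 60.0)],
        arrival_rate_fibril=0.30,
        arrival_rate_bg=0.20,
        n_frames=120,
        image_shape=(96, 96),
        photons_per_frame=800.0,
        bg_photons_px=5.0,
        read_noise=1.0,
        bleach=BleachModel.disabled(),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_geometry(small_truth):
    mask, segments = make_fibril_geometry(11, 2, small_truth.image_shape)
    return mask, segments


@pytest.fixture(scope="session")
def small_events(small_truth, small_geometry):
    mask, _ = small_geometry
    return simulate_event_list(small_truth, fibril_mask=mask)


@pytest.fixture(scope="session")
def small_movie(small_truth, small_events):
    return render_movie(small_events, small_truth)


@pytest.fixture(scope="session")
def sparse_truth():
    """Imaging conditions for a guaranteed-sparse field (emitters >= 5 px apart)."""
    return SimulationTruth(
        populations=[PopulationSpec(1.0, 20.0)],
        arrival_rate_fibril=0.0,
        n_frames=150,
        image_shape=(96, 96),
        photons_per_frame=800.0,
        bg_photons_px=5.0,
        read_noise=1.0,
        bleach=BleachModel.disabled(),
        seed=21,
    )


@pytest.fixture(scope="session")
def sparse_events(sparse_truth):
    """50 emitters on a jittered grid: concurrent spots never overlap."""
    from smdwell.simulate import TrueEvent

    rng = np.random.default_rng(sparse_truth.seed)
    events = []
    grid = [(x, y) for y in range(10, 90, 11) for x in range(10, 90, 11)][:50]
    for x0, y0 in grid:
        x = x0 + rng.uniform(-2, 2)
        y = y0 + rng.uniform(-2, 2)
        start = int(rng.integers(1, 100))
        dwell = float(np.ceil(rng.exponential(20.0)))
        dwell = min(dwell, sparse_truth.n_frames - start - 2)
        if dwell < 1:
            dwell = 1.0
        events.append(TrueEvent(x, y, start, dwell, dwell, int(dwell), 0, "background"))
    return events


@pytest.fixture(scope="session")
def sparse_movie(sparse_truth, sparse_events):
    return render_movie(sparse_events, sparse_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
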