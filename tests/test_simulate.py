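"""Ground-truth generator: dwell statistics, geometry, and rendering."""

import dataclasses

import numpy as np
import pytest
from scipy import stats
from skimage.measure import label

from smdwell.simulate import (
    BleachModel,
    PopulationSpec,
    SimulationTruth,
    TrueEvent,
    make_fibril_geometry,
    render_movie,
    simulate_event_list,
)


def _truth(**kwargs):
    defaults = dict(
        populations=[PopulationSpec(1.0, 15.0)],
        arrival_rate_fibril=4.0,
        n_frames=2500,
        bleach=BleachModel.disabled(),
        seed=42,
    )
    defaults.update(kwargs)
    return SimulationTruth(**defaults)


class TestValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            _truth(populations=[PopulationSpec(0.5, 15.0), PopulationSpec(0.4, 60.0)])

    def test_rejects_short_movies(self):
        with pytest.raises(ValueError, match="n_frames"):
            _truth(n_frames=1)

    def test_immobilized_takes_no_tau(self):
        with pytest.raises(ValueError):
            PopulationSpec(1.0, tau_s=15.0, immobilized=True)

    def test_bleach_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            BleachModel((195.0, 1100.0), (0.5, 0.6))


class TestEventList:
    def test_zero_rates_give_empty_list(self):
        truth = _truth(arrival_rate_fibril=0.0, arrival_rate_bg=0.0)
        assert simulate_event_list(truth) == []

    def test_seed_determinism(self):
        truth = _truth()
        assert simulate_event_list(truth) == simulate_event_list(truth)

    def test_immobilized_dwells_reproduce_bleach_mean(self):
        # immobilized molecules disappear only by photobleaching: mean
        # observed dwell is the bleach-mixture mean 0.5*195 + 0.5*1100
        truth = _truth(
            populations=[PopulationSpec(1.0, immobilized=True)],
            bleach=BleachModel.oxygen_scavenged(),
            arrival_rate_fibril=40.0,  # ~1e5 events
        )
        events = simulate_event_list(truth)
        assert len(events) > 90_000
        dwells = np.array([e.observed_dwell_s for e in events])
        # Monte-Carlo oracle from the bleach model directly
        oracle = BleachModel.oxygen_scavenged().sample(np.random.default_rng(0), 100_000)
        assert abs(oracle.mean() - 647.5) < 15.0
        sem = dwells.std() / np.sqrt(len(dwells))
        assert abs(dwells.mean() - 647.5) < 5 * sem

    def test_exponential_population_mean(self):
        truth = _truth(arrival_rate_fibril=10.0)
        dwells = np.array([e.true_dwell_s for e in simulate_event_list(truth)])
        assert abs(dwells.mean() - 15.0) < 5 * 15.0 / np.sqrt(len(dwells))

    def test_observed_never_exceeds_true_dwell(self):
        truth = _truth(
            populations=[PopulationSpec(0.7, 30.0), PopulationSpec(0.3, immobilized=True)],
            bleach=BleachModel.oxygen_scavenged(),
        )
        for e in simulate_event_list(truth):
            assert e.observed_dwell_s <= e.true_dwell_s
            assert e.observed_dwell_s > 0
            assert e.n_frames_obs >= 1

    def test_mixture_survival_matches_ks(self):
        # empirical dwell distribution vs S(t) = sum f_j exp(-t/tau_j)
        truth = _truth(
            populations=[PopulationSpec(0.8, 15.0), PopulationSpec(0.2, 120.0)],
            arrival_rate_fibril=4.0,
        )
        dwells = np.array([e.true_dwell_s for e in simulate_event_list(truth)])[:10_000]
        cdf = lambda t: 1 - 0.8 * np.exp(-t / 15.0) - 0.2 * np.exp(-t / 120.0)
        assert stats.kstest(dwells, cdf).pvalue > 1e-3

    def test_bleach_mixture_survival_matches_ks(self):
        truth = _truth(
            populations=[PopulationSpec(1.0, immobilized=True)],
            bleach=BleachModel.oxygen_scavenged(),
            arrival_rate_fibril=4.0,
        )
        dwells = np.array([e.observed_dwell_s for e in simulate_event_list(truth)])[:10_000]
        bleach = BleachModel.oxygen_scavenged()
        cdf = lambda t: 1 - bleach.survival(t)
        assert stats.kstest(dwells, cdf).pvalue > 1e-3

    @pytest.mark.parametrize("rate", [0.5, 2.0, 8.0])
    def test_event_count_scales_with_rate(self, rate):
        truth = _truth(arrival_rate_fibril=rate, n_frames=1000)
        n = len(simulate_event_list(truth))
        expected = rate * 1000
        assert abs(n - expected) < 3 * np.sqrt(expected)

    def test_events_constrained_to_support_mask(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:12, :] = True
        truth = _truth(
            arrival_rate_fibril=1.0, arrival_rate_bg=1.0, n_frames=200,
            image_shape=(64, 64),
        )
        for e in simulate_event_list(truth, fibril_mask=mask):
            on_mask = mask[int(round(e.y_px)) % 64, int(round(e.x_px)) % 64]
            if e.region == "fibril":
                assert 9.5 <= e.y_px < 12.5


class TestFibrilGeometry:
    def test_zero_fibrils_empty_mask(self):
        mask, segments = make_fibril_geometry(0, 0, (128, 128))
        assert not mask.any()
        assert segments == []

    def test_component_count_matches_fibril_count(self):
        mask, segments = make_fibril_geometry(3, 3, (256, 256))
        assert len(segments) == 3
        assert label(mask, connectivity=2).max() == 3

    def test_seed_determinism(self):
        a, _ = make_fibril_geometry(5, 4, (128, 128))
        b, _ = make_fibril_geometry(5, 4, (128, 128))
        assert np.array_equal(a, b)

    def test_rejects_bad_shape(self):
        with pytest.raises(ValueError):
            make_fibril_geometry(0, 1, (0, 128))


class TestRenderMovie:
    def test_empty_noiseless_movie_is_zero(self):
        truth = _truth(
            arrival_rate_fibril=0.0, n_frames=5, image_shape=(32, 32),
            bg_photons_px=0.0, read_noise=0.0, shot_noise=False,
        )
        stack = render_movie([], truth)
        assert np.all(stack.data == 0)

    def test_noiseless_emitter_conserves_photons(self):
        truth = _truth(
            arrival_rate_fibril=0.0, n_frames=3, image_shape=(32, 32),
            bg_photons_px=0.0, read_noise=0.0, shot_noise=False,
            photons_per_frame=500.0, psf_sigma_px=1.3,
        )
        ev = TrueEvent(16.0, 16.0, 0, np.inf, 1e9, 10**9, 0, "fibril")
        stack = render_movie([ev], truth)
        sums = stack.data.sum(axis=(1, 2))
        assert np.allclose(sums, 500.0, atol=1e-6)

    def test_linear_drift_displaces_centroid(self):
        from scipy.ndimage import center_of_mass

        truth = _truth(
            arrival_rate_fibril=0.0, n_frames=1000, image_shape=(40, 40),
            bg_photons_px=0.0, read_noise=0.0, shot_noise=False,
            drift_px_per_frame=(0.01, 0.0),
        )
        ev = TrueEvent(10.0, 20.0, 0, np.inf, 1e9, 10**9, 0, "fibril")
        stack = render_movie([ev], truth)
        x0 = center_of_mass(stack.data[0])[1]
        x999 = center_of_mass(stack.data[999])[1]
        assert abs((x999 - x0) - 9.99) < 0.01

    def test_render_determinism(self, small_truth, small_events):
        a = render_movie(small_events, small_truth)
        b = render_movie(small_events, small_truth)
        assert np.array_equal(a.data, b.data)

    def test_out_of_bounds_event_rejected(self):
        truth = _truth(arrival_rate_fibril=0.0, n_frames=3, image_shape=(16, 16))
        ev = TrueEvent(50.0, 8.0, 0, 5.0, 5.0, 5, 0, "fibril")
        with pytest.raises(ValueError, match="outside image bounds"):
            render_movie([ev], truth)

    def test_drifted_out_emitters_counted_not_fatal(self):
        truth = _truth(
            arrival_rate_fibril=0.0, n_frames=200, image_shape=(16, 16),
            drift_px_per_frame=(0.5, 0.0), bg_photons_px=0.0, read_noise=0.0,
            shot_noise=False,
        )
        ev = TrueEvent(8.0, 8.0, 0, np.inf, 1e9, 10**9, 0, "fibril")
        with pytest.warns(UserWarning, match="drifted outside"):
            stack = render_movie([ev], truth)
        assert stack.n_clipped_emitters > 0
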