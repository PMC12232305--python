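"""Synthetic FLIM image generation: channels, mixing, decays, fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flimforge.axes import TimeAxis
from flimforge.irf import delta_irf
from flimforge.simulate import (
    assign_channel_lifetimes,
    flower_fixture,
    ground_truth_lifetime,
    normalize_decay,
    perlin_fraction_maps,
    scale_to_photon_range,
    simulate_flim_image,
    simulate_pixel_decay,
    subsample_photons,
    synth_intensity_channels,
    two_region_fixture,
    uniform_and_single_pixel_fixture,
)


class TestIntensityChannels:
    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_coverage_at_least_five_percent(self, seed):
        chans = synth_intensity_channels((32, 32), 3, seed=seed)
        union = np.zeros((32, 32), dtype=bool)
        for c in chans:
            union |= c > 0
        assert union.mean() >= 0.05

    def test_single_channel(self):
        assert len(synth_intensity_channels((16, 16), 1, seed=0)) == 1

    def test_determinism(self):
        a = synth_intensity_channels((16, 16), 2, seed=4)
        b = synth_intensity_channels((16, 16), 2, seed=4)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            synth_intensity_channels((4, 4), 1, seed=0)


class TestChannelLifetimes:
    def test_bases_within_range(self):
        chans = synth_intensity_channels((16, 16), 4, seed=0)
        for seed in range(50):
            for s in assign_channel_lifetimes(chans, seed=seed):
                assert 0.1 <= s.base_lifetime <= 10.0
                assert 0.2 <= s.variability <= 2.0

    def test_per_pixel_lifetimes_clipped(self):
        chans = synth_intensity_channels((16, 16), 4, seed=1)
        for s in assign_channel_lifetimes(chans, seed=3):
            assert s.lifetime_map.min() >= 0.1
            assert s.lifetime_map.max() <= 10.0

    def test_zero_variability_override(self):
        chans = synth_intensity_channels((16, 16), 2, seed=2)
        for s in assign_channel_lifetimes(chans, seed=0, variability_override=0.0):
            assert np.all(s.lifetime_map == s.base_lifetime)


class TestFractionMaps:
    def test_sum_to_one_everywhere(self):
        fm = perlin_fraction_maps((24, 24), 4, seed=0)
        assert np.allclose(fm.fractions.sum(axis=0), 1.0, atol=1e-9)
        assert fm.fractions.min() >= 0

    def test_single_channel_is_unity(self):
        fm = perlin_fraction_maps((16, 16), 1, seed=0)
        assert np.allclose(fm.fractions, 1.0)

    def test_spatially_smoother_than_shuffled(self, rng):
        f = perlin_fraction_maps((64, 64), 2, seed=1).fractions[0]

        def lag1_autocorr(img):
            x = img - img.mean()
            return float(np.sum(x[:, :-1] * x[:, 1:]) / np.sum(x * x))

        shuffled = rng.permutation(f.ravel()).reshape(f.shape)
        assert lag1_autocorr(f) > lag1_autocorr(shuffled)


class TestPixelDecay:
    def test_mono_exponential_bin_ratio(self, axis, delta):
        d = simulate_pixel_decay([1.0], [2.0], delta, 1000, noise=False)
        ratios = d[1:] / d[:-1]
        assert np.allclose(ratios, np.exp(-axis.bin_width / 2.0), rtol=1e-12)

    def test_zero_photons(self, delta):
        assert simulate_pixel_decay([1.0], [3.0], delta, 0).sum() == 0

    def test_noiseless_sum_hits_target(self, delta):
        d = simulate_pixel_decay([0.3, 0.7], [1.0, 5.0], delta, 500, noise=False)
        assert d.sum() == pytest.approx(500, abs=0.5)

    def test_poisson_mean_matches_noiseless(self, delta):
        mean_curve = simulate_pixel_decay([1.0], [2.5], delta, 100, noise=False)
        rng = np.random.default_rng(11)
        reps = 10_000
        acc = np.zeros_like(mean_curve)
        for _ in range(reps):
            acc += simulate_pixel_decay([1.0], [2.5], delta, 100, seed=rng, noise=True)
        sample_mean = acc / reps
        se = np.sqrt(np.maximum(mean_curve, 1e-12) / reps)
        nonzero = mean_curve > 1e-3
        z = (sample_mean[nonzero] - mean_curve[nonzero]) / se[nonzero]
        assert np.max(np.abs(z)) < 4.0
        assert np.mean(np.abs(z) < 3.0) > 0.99

    def test_log_linear_fit_recovers_tau(self, axis, delta):
        """Oracle equivalence: least-squares on log counts inverts the
        noiseless mono-exponential simulation to 1e-6 relative."""
        for tau in (0.7, 2.0, 6.5):
            d = simulate_pixel_decay([1.0], [tau], delta, 10_000, noise=False)
            keep = d > 0
            slope = np.polyfit(axis.times[keep], np.log(d[keep]), 1)[0]
            assert -1.0 / slope == pytest.approx(tau, rel=1e-6)

    def test_mismatched_lengths_rejected(self, delta):
        with pytest.raises(ValueError):
            simulate_pixel_decay([1.0], [1.0, 2.0], delta, 100)

    def test_negative_photons_rejected(self, delta):
        with pytest.raises(ValueError):
            simulate_pixel_decay([1.0], [1.0], delta, -5)


class TestNormalizeDecay:
    def test_max_is_one(self, rng):
        d = rng.poisson(50, size=64)
        assert normalize_decay(d).max() == 1.0

    def test_all_zero_passthrough(self):
        assert np.all(normalize_decay(np.zeros(16)) == 0)

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        d = np.arange(1.0, 11.0)
        assert np.allclose(normalize_decay(d * scale), normalize_decay(d))


class TestGroundTruthLifetime:
    def test_single_component(self):
        assert ground_truth_lifetime([1.0], [3.2]) == pytest.approx(3.2)

    def test_equal_mixture(self):
        assert ground_truth_lifetime([0.5, 0.5], [2.0, 4.0]) == pytest.approx(3.0)

    def test_weighted_mixture(self):
        assert ground_truth_lifetime([0.25, 0.75], [1.0, 5.0]) == pytest.approx(4.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ground_truth_lifetime([], [])

    def test_convex_hull_property(self, rng):
        for _ in range(100):
            a = rng.dirichlet(np.ones(3))
            tau = rng.uniform(0.1, 10.0, 3)
            gt = ground_truth_lifetime(a, tau)
            assert tau.min() - 1e-12 <= gt <= tau.max() + 1e-12


class TestPhotonScaling:
    def test_high_regime_bounds(self, rng):
        comp = rng.uniform(0, 5, size=(32, 32))
        mask = comp > 1
        targets = scale_to_photon_range(comp, "high", mask)
        assert targets[mask].min() >= 100 and targets[mask].max() <= 2500

    def test_background_is_zero(self, rng):
        comp = rng.uniform(0, 5, size=(16, 16))
        mask = comp > 2.5
        assert np.all(scale_to_photon_range(comp, "low", mask)[~mask] == 0)

    def test_affine_endpoints(self):
        comp = np.array([[1.0, 2.0], [3.0, 4.0]])
        mask = np.ones((2, 2), dtype=bool)
        t = scale_to_photon_range(comp, "high", mask)
        assert t[0, 0] == 100 and t[1, 1] == 2500

    def test_constant_composite_midpoint(self):
        comp = np.full((4, 4), 2.0)
        mask = np.ones((4, 4), dtype=bool)
        assert np.all(scale_to_photon_range(comp, "low", mask) == 55)


class TestSimulateImage:
    def test_stack_shape_time_first(self):
        stack, _ = simulate_flim_image(shape=(16, 16), n_channels=2, seed=0)
        assert stack.counts.shape == (256, 16, 16)

    def test_ground_truth_range(self):
        _, truth = simulate_flim_image(shape=(24, 24), n_channels=3, seed=1)
        fg = truth.tau[~truth.background_mask]
        assert fg.min() >= 0.1 and fg.max() <= 10.0
        assert np.all(truth.tau[truth.background_mask] == 0)

    def test_determinism(self):
        a, ta = simulate_flim_image(shape=(16, 16), n_channels=2, seed=7)
        b, tb = simulate_flim_image(shape=(16, 16), n_channels=2, seed=7)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(ta.tau, tb.tau)


class TestFixtures:
    def test_flower_constants(self):
        for stack, truth in flower_fixture(3, seed=2):
            center = truth.tau[7:9, 7:9]
            assert np.all(center == 1.0)
            petals = truth.tau[(truth.tau > 0) & (truth.tau != 1.0)]
            assert petals.min() >= 4.0 and petals.max() <= 6.0
            assert stack.meta["photon_target"] == 20

    def test_single_pixel_fixture(self):
        pairs = uniform_and_single_pixel_fixture(2, seed=3)
        for full, masked, tau in pairs:
            assert full.counts.shape[1:] == (28, 28)
            assert 0.4 <= tau <= 6.0
            nz = np.argwhere(masked.total_counts() > 0)
            assert nz.shape == (1, 2) and tuple(nz[0]) == (10, 10)
            assert np.array_equal(masked.counts[:, 10, 10], full.counts[:, 10, 10])

    def test_two_region_fixture_lifetimes(self):
        for stack, truth in two_region_fixture(2, seed=1):
            assert set(np.unique(truth.tau)) == {1.0, 4.0}
            assert not truth.background_mask.any()


class TestSubsample:
    def _stack(self, seed=0):
        stack, _ = simulate_flim_image(shape=(12, 12), n_channels=2, seed=seed)
        return stack

    def test_exact_targets(self):
        stack = self._stack()
        targets = np.minimum(stack.total_counts(), 30)
        thin = subsample_photons(stack, targets, seed=1)
        assert np.array_equal(thin.total_counts(), targets)

    def test_target_equal_total_unchanged(self):
        stack = self._stack(1)
        thin = subsample_photons(stack, stack.total_counts(), seed=0)
        assert np.array_equal(thin.counts, stack.counts)

    def test_excess_target_names_pixel(self):
        stack = self._stack(2)
        targets = stack.total_counts() + 1
        with pytest.raises(ValueError, match=r"pixel \(0, 0\)"):
            subsample_photons(stack, targets, seed=0)

    def test_thinning_preserves_proportions_in_expectation(self, delta, axis):
        from flimforge.simulate import FLIMStack

        hist = simulate_pixel_decay([1.0], [2.0], delta, 400, seed=5).astype(np.int64)
        stack = FLIMStack(counts=hist[:, None, None], axis=axis)
        target = np.array([[40]])
        reps = 10_000
        acc = np.zeros_like(hist, dtype=float)
        for i in range(reps):
            acc += subsample_photons(stack, target, seed=i).counts[:, 0, 0]
        mean = acc / reps
        expected = hist * (40 / hist.sum())
        # hypergeometric per-bin variance, 3 SE band
        n, total = 40, hist.sum()
        p = hist / total
        var = n * p * (1 - p) * (total - n) / (total - 1)
        se = np.sqrt(np.maximum(var, 1e-12) / reps)
        z = (mean - expected) / np.maximum(se, 1e-12)
        assert np.max(np.abs(z[hist > 0])) < 4.0
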