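"""Coupon deposition, spot sampling, and spectrum simulation."""

import math

import numpy as np
import pytest

from rcvkit import synthetic as syn
from rcvkit.synthetic import (
    DepositionInfeasibleError,
    DepositionProfile,
    InstrumentProfile,
    SpotOutOfBoundsError,
    circle_overlap_area,
    generate_coupon,
    sample_random_spots,
    sample_spot,
    simulate_measurement,
)


class TestGenerateCoupon:
    def test_zero_target_gives_empty_surface(self):
        surf = generate_coupon(0.0, seed=0)
        assert len(surf.pattern.positions) == 0
        assert surf.mean_density == 0.0
        assert sample_spot(surf, (12.0, 12.0)) == 0.0

    @pytest.mark.parametrize("inhomogeneity", [0.0, 0.1, 0.5])
    def test_mean_density_hits_target(self, inhomogeneity):
        surf = generate_coupon(0.6, DepositionProfile(inhomogeneity=inhomogeneity), seed=3)
        assert surf.mean_density == pytest.approx(0.6, rel=0.02)

    def test_droplet_parameters_within_ranges(self, hand_coupon):
        p = hand_coupon.pattern
        assert len(p.positions) <= p.max_droplets
        assert (p.volumes >= p.volume_range[0]).all()
        assert (p.volumes <= p.volume_range[1]).all()
        assert (p.positions >= 0).all()
        assert (p.positions[:, 0] <= hand_coupon.width).all()
        assert (p.positions[:, 1] <= hand_coupon.height).all()

    def test_seed_determinism(self):
        a = generate_coupon(0.6, seed=11)
        b = generate_coupon(0.6, seed=11)
        np.testing.assert_array_equal(a.pattern.positions, b.pattern.positions)
        np.testing.assert_array_equal(a.pattern.volumes, b.pattern.volumes)

    def test_infeasible_target_raises(self):
        # max mass = 5200 droplets x 10 nL x conc; ask for far more
        with pytest.raises(DepositionInfeasibleError):
            generate_coupon(100.0, DepositionProfile(), seed=0)

    def test_mass_conservation_exact(self, hand_coupon):
        # every droplet disc lies fully on the coupon (checked above), so
        # the area integral of the density field equals the mass sum
        assert hand_coupon.mean_density * hand_coupon.area_cm2 == pytest.approx(
            hand_coupon.pattern.total_mass, abs=0.0, rel=1e-12
        )


class TestSampleSpot:
    def test_single_droplet_inside_footprint(self):
        # one droplet of mass m fully inside footprint of area a
        # -> density m / (a * 0.01) ug/cm^2
        pattern = syn.DropletPattern(
            positions=[[12.5, 12.5]], volumes=[8.0], solution_concentration=1e-3
        )
        surf = syn.CouponSurface(25, 25, pattern, target_density=0.0)
        m = 8.0 * 1e-3
        a = 1.76
        assert sample_spot(surf, (12.5, 12.5), a) == pytest.approx(m / (a * 0.01))

    def test_out_of_bounds_footprint_raises(self, hand_coupon):
        with pytest.raises(SpotOutOfBoundsError):
            sample_spot(hand_coupon, (0.1, 12.0))

    def test_dense_grid_spot_matches_mean_density(self):
        # dense uniform grid: every interior spot sees ~the mean density
        # (oracle = total mass / total area)
        pitch = 0.25
        xs = np.arange(pitch / 2, 25, pitch)
        gx, gy = np.meshgrid(xs, xs)
        pattern = syn.DropletPattern(
            positions=np.column_stack([gx.ravel(), gy.ravel()]),
            volumes=np.full(gx.size, 5.0),
            solution_concentration=1e-4,
            max_droplets=20_000,
        )
        surf = syn.CouponSurface(25, 25, pattern, target_density=0.0)
        for center in [(12.5, 12.5), (7.3, 18.2)]:
            assert sample_spot(surf, center) == pytest.approx(surf.mean_density, rel=0.02)

    def test_deterministic(self, hand_coupon):
        assert sample_spot(hand_coupon, (10.0, 10.0)) == sample_spot(
            hand_coupon, (10.0, 10.0)
        )

    def test_unbiased_over_random_spots(self, hand_coupon):
        d = sample_random_spots(hand_coupon, 1000, seed=5)
        se = d.std(ddof=1) / math.sqrt(len(d))
        assert abs(d.mean() - 0.6) <= 3 * se

    def test_hand_mode_rsd_in_observed_band(self, hand_coupon):
        d = sample_random_spots(hand_coupon, 1000, seed=9)
        rsd = 100 * d.std(ddof=1) / d.mean()
        assert 27 <= rsd <= 53

    def test_grid_mode_much_more_uniform_than_hand(self, grid_coupon):
        d = sample_random_spots(grid_coupon, 300, seed=9)
        rsd = 100 * d.std(ddof=1) / d.mean()
        assert rsd < 27


class TestCircleOverlap:
    def test_limits(self):
        assert circle_overlap_area(5.0, 1.0, 2.0) == 0.0
        assert circle_overlap_area(0.0, 1.0, 2.0) == pytest.approx(math.pi)

    def test_partial_overlap_matches_monte_carlo(self):
        r1, r2, d = 1.0, 0.6, 1.2
        rng = np.random.default_rng(0)
        pts = rng.uniform(-r2, r2, size=(200_000, 2))
        inside2 = (pts**2).sum(axis=1) <= r2**2
        inside1 = ((pts[:, 0] - d) ** 2 + pts[:, 1] ** 2) <= r1**2
        mc = (inside1 & inside2).mean() * (2 * r2) ** 2
        assert circle_overlap_area(d, r1, r2) == pytest.approx(mc, rel=0.02)


class TestSimulateMeasurement:
    def test_zero_density_no_noise_is_flat_zero(self, signature, quiet_instrument):
        s = simulate_measurement(0.0, signature, quiet_instrument, seed=0)
        np.testing.assert_array_equal(s.absorbance, 0.0)

    def test_peak_height_linear_in_density(self, signature, quiet_instrument):
        s1 = simulate_measurement(0.7, signature, quiet_instrument, seed=0)
        s2 = simulate_measurement(1.4, signature, quiet_instrument, seed=0)
        np.testing.assert_allclose(s2.absorbance, 2 * s1.absorbance, atol=1e-15)

    def test_scan_averaging_reduces_noise_by_sqrt_scans(self, signature):
        # flat-region channel: empirical SD over reps ~ sigma / sqrt(16)
        inst = InstrumentProfile(
            wavenumber_min=3500, wavenumber_max=3600, baseline_shift_sd=0.0,
            noise_sd_per_scan=0.004, scans_per_spectrum=16,
        )
        rng = np.random.default_rng(42)
        vals = [
            simulate_measurement(0.0, signature, inst, rng=rng).absorbance[5]
            for _ in range(4000)
        ]
        sd = np.std(vals, ddof=1)
        assert sd == pytest.approx(0.004 / 4, rel=0.08)

    def test_negative_density_rejected(self, signature):
        with pytest.raises(ValueError):
            simulate_measurement(-0.1, signature)


class TestSpectraCollections:
    def test_calibration_set_bookkeeping(self, signature, narrow_instrument):
        levels = [0.5, 1.0, 1.5, 2.0, 2.5, 3.0]
        spectra = syn.generate_calibration_set(levels, 5, signature, narrow_instrument, seed=0)
        assert len(spectra) == 30
        assert sorted({s.true_density for s in spectra}) == levels
        assert all(s.n_scans_averaged == 16 for s in spectra)

    def test_empty_levels_rejected(self, signature):
        with pytest.raises(ValueError):
            syn.generate_calibration_set([], 3, signature)

    def test_noise_free_replicates_identical(self, signature, quiet_instrument):
        spectra = syn.generate_calibration_set([1.0], 3, signature, quiet_instrument, seed=0)
        np.testing.assert_array_equal(spectra[0].absorbance, spectra[1].absorbance)
        np.testing.assert_array_equal(spectra[1].absorbance, spectra[2].absorbance)

    def test_pseudo_blanks_share_truth_and_count(self, signature, narrow_instrument):
        reps = syn.generate_pseudo_blank_replicates(0.3, 10, signature, narrow_instrument, seed=0)
        assert len(reps) == 10
        assert all(s.true_density == 0.3 for s in reps)

    def test_pseudo_blanks_noise_free_identical(self, signature, quiet_instrument):
        reps = syn.generate_pseudo_blank_replicates(0.3, 10, signature, quiet_instrument, seed=0)
        for s in reps[1:]:
            np.testing.assert_array_equal(s.absorbance, reps[0].absorbance)

    def test_pseudo_blanks_need_two(self, signature):
        with pytest.raises(ValueError):
            syn.generate_pseudo_blank_replicates(0.3, 1, signature)
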