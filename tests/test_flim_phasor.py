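"""FLIM pipeline: registration, background, IRF, phasors, unmixing."""

import math

import numpy as np
import pytest

from cryoblur import flim_phasor as fp
from cryoblur import synthetic as syn


def make_stack(counts, laser_period=12.5):
    counts = np.asarray(counts)
    return fp.TCSPCStack(counts, laser_period / counts.shape[3], laser_period)


class TestTCSPCStack:
    def test_validation(self):
        with pytest.raises(ValueError):
            fp.TCSPCStack(np.zeros((4, 4, 8)), 0.1, 12.5)  # not 4D
        with pytest.raises(ValueError):
            fp.TCSPCStack(-np.ones((1, 4, 4, 8)), 0.1, 12.5)
        with pytest.raises(ValueError):
            fp.TCSPCStack(np.zeros((1, 4, 4, 8)), 2.0, 12.5)  # bins exceed period

    def test_omega_and_centers(self):
        stack = make_stack(np.zeros((1, 4, 4, 10)))
        assert stack.omega == pytest.approx(2 * math.pi / 12.5)
        assert stack.bin_centers[0] == pytest.approx(0.625)


class TestRegistration:
    def test_single_frame_identity(self, mono_stack):
        stack, _, _ = mono_stack
        reg, shifts, dropped = fp.register_stack(stack)
        assert dropped == 0
        assert np.array_equal(shifts, np.zeros((1, 2), dtype=int))
        assert np.array_equal(reg.counts, stack.counts)

    def test_recovers_planted_integer_shifts_exactly(self):
        spec = syn.lifea2_cryo(seed=8, drift_per_frame=(3.0, -2.0), n_frames=2)
        stack, truth = syn.generate_tcspc_stack(spec)
        reg, shifts, dropped = fp.register_stack(stack)
        assert tuple(shifts[1]) == (-3, 2)  # opposite of the planted drift
        # photon bookkeeping is exact
        assert dropped == stack.total_photons() - reg.total_photons()
        expected_drop = int(
            stack.counts[1].sum()
            - fp._shift_frame(stack.counts[1], -3, 2).sum()
        )
        assert dropped == expected_drop

    def test_subpixel_drift_rounds_to_zero(self):
        spec = syn.lifea2_cryo(seed=8, drift_per_frame=(0.4, 0.0), n_frames=2)
        stack, _ = syn.generate_tcspc_stack(spec)
        _, shifts, dropped = fp.register_stack(stack)
        assert tuple(shifts[1]) == (0, 0)
        assert dropped == 0

    def test_never_creates_photons(self, cryo_scene):
        stack, _ = cryo_scene
        reg, _, dropped = fp.register_stack(stack)
        assert reg.total_photons() <= stack.total_photons()
        assert dropped >= 0


class TestBackground:
    def test_uniform_image_exact(self):
        counts = np.full((1, 40, 40, 64), 2, dtype=np.uint32)
        stack = make_stack(counts)
        assert fp.estimate_background_image(stack) == pytest.approx(2 * 64)

    def test_poisson_background_within_3_sigma(self, cryo_scene):
        stack, truth = cryo_scene
        spec = truth["spec"]
        true_per_px = spec.background_rate * spec.n_frames
        est = fp.estimate_background_image(stack)
        sigma = math.sqrt(true_per_px / 21**2)
        assert abs(est - true_per_px) < max(3 * sigma, 0.15 * true_per_px)

    def test_dead_pixel_does_not_attract_window(self):
        # a single zero pixel inside a bright region is the raw minimum, but
        # the median prefilter keeps the window in the genuinely dark area
        rng = np.random.default_rng(0)
        counts = rng.poisson(3, size=(1, 64, 64, 16)).astype(np.uint32)
        dark_mean = counts.sum(axis=(0, 3)).mean()
        counts[0, 28:44, 28:44, :] += 200
        counts[0, 36, 36, :] = 0
        stack = make_stack(counts)
        est = fp.estimate_background_image(stack)
        assert est == pytest.approx(dark_mean, rel=0.25)

    def test_histogram_floor_recovery(self):
        # monoexponential + known flat offset per bin
        profile = syn.decay_profile(0.5, 256, 12.5)  # short lifetime: real floor
        offset = 50.0
        hist = profile * 2e5 + offset
        counts = hist[None, None, None, :] * np.ones((1, 4, 4, 1)) / 16.0
        stack = make_stack(counts)
        per_bin, total = fp.estimate_background_histogram(stack)
        assert per_bin == pytest.approx(offset, rel=0.25)
        assert total == pytest.approx(per_bin * 256)

    def test_zero_background_near_zero(self):
        # short lifetime (pure active state) so the decay truly dies within
        # the period and both estimators can see an (absent) floor
        spec = syn.SceneSpec(
            shape=(48, 48), n_frames=1, background_rate=0.0,
            drift_per_frame=(0.0, 0.0), donor_only_fraction=0.0,
            blobs=(syn.Blob((34, 34), 8, 1.0, 1000.0),), seed=6,
        )
        stack, _ = syn.generate_tcspc_stack(spec)
        est = fp.estimate_background(stack)
        assert est.image_based == pytest.approx(0.0, abs=1e-6)
        assert est.histogram_based < 0.01 * stack.total_photons()

    def test_consistency_flag(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(2.0, size=(1, 48, 48, 64)).astype(np.uint32)
        est = fp.estimate_background(make_stack(counts))
        assert est.consistent  # pure flat background: both estimators agree


class TestIRF:
    def test_delta_irf_identity(self, mono_stack):
        stack, _, _ = mono_stack
        irf = fp.estimate_irf(stack)
        assert irf.shift_ns == pytest.approx(0.0, abs=0.05)
        assert irf.width_ns == pytest.approx(0.0, abs=0.05)
        assert fp.IRFEstimate().phasor(stack.omega) == pytest.approx(1.0 + 0j)

    def test_recovers_gaussian_irf(self):
        spec = syn.SceneSpec(
            shape=(16, 16), n_frames=1, background_rate=0.0,
            drift_per_frame=(0.0, 0.0), donor_only_fraction=1.0,
            irf_shift=0.5, irf_width=0.3,
            blobs=(syn.Blob((8, 8), 6, 0.0, 2000.0),), seed=2,
        )
        stack, _ = syn.generate_tcspc_stack(spec)
        irf = fp.estimate_irf(stack)
        assert irf.shift_ns == pytest.approx(0.5, rel=0.1)
        assert irf.width_ns == pytest.approx(0.3, rel=0.15)

    def test_correction_returns_to_semicircle(self):
        spec = syn.SceneSpec(
            shape=(16, 16), n_frames=1, background_rate=0.0,
            drift_per_frame=(0.0, 0.0), donor_only_fraction=1.0,
            irf_shift=0.5, irf_width=0.3,
            blobs=(syn.Blob((8, 8), 6, 0.0, 2000.0),), seed=2,
        )
        stack, _ = syn.generate_tcspc_stack(spec, noise_free=True)
        irf = fp.estimate_irf(stack)
        ph = fp.phasor_transform(stack, irf=irf)
        sel = ph.mask & (ph.photons > 100)
        assert np.nanmax(ph.semicircle_residual()[sel]) < 1e-3

    def test_too_few_photons_identity(self):
        counts = np.zeros((1, 4, 4, 64), dtype=np.uint32)
        counts[0, 0, 0, 0] = 5
        with pytest.warns(UserWarning):
            irf = fp.estimate_irf(make_stack(counts))
        assert irf.shift_ns == 0.0 and irf.width_ns == 0.0


class TestPhasorTransform:
    def test_monoexponential_closed_form(self):
        omega = 2 * math.pi / 12.5
        for tau in (0.9, 3.5, 3.71, 12.5 / (2 * math.pi)):  # last: omega*tau = 1
            profile = syn.decay_profile(tau, 512, 12.5)
            counts = profile[None, None, None, :] * 1e6
            ph = fp.phasor_transform(make_stack(counts))
            x = omega * tau
            assert ph.re[0, 0] == pytest.approx(1 / (1 + x * x), abs=2e-4)
            assert ph.im[0, 0] == pytest.approx(x / (1 + x * x), abs=2e-4)

    def test_instantaneous_decay_at_origin_of_lag(self):
        counts = np.zeros((1, 1, 1, 256))
        counts[0, 0, 0, 0] = 1e4
        ph = fp.phasor_transform(make_stack(counts))
        assert ph.re[0, 0] == pytest.approx(1.0, abs=1e-3)
        assert ph.im[0, 0] == pytest.approx(0.0, abs=0.02)

    def test_mixture_linearity(self):
        p1 = syn.decay_profile(0.9, 256, 12.5)
        p2 = syn.decay_profile(3.5, 256, 12.5)
        ph1 = fp.phasor_transform(make_stack(p1[None, None, None, :] * 1e6))
        ph2 = fp.phasor_transform(make_stack(p2[None, None, None, :] * 1e6))
        mix = fp.phasor_transform(
            make_stack((0.5 * p1 + 0.5 * p2)[None, None, None, :] * 1e6)
        )
        assert mix.complex[0, 0] == pytest.approx(
            0.5 * ph1.complex[0, 0] + 0.5 * ph2.complex[0, 0], rel=1e-12
        )

    def test_semicircle_residual_noise_free(self, mono_stack):
        stack, truth, _ = mono_stack
        ph = fp.phasor_transform(stack)
        sel = ph.mask & (truth["expected_total"] > 0)
        assert np.nanmax(ph.semicircle_residual()[sel]) < 1e-3

    def test_nonpositive_pixels_masked(self):
        counts = np.zeros((1, 2, 2, 64))
        counts[0, 0, 0, :] = 1.0
        ph = fp.phasor_transform(make_stack(counts), background=0.5)
        assert ph.mask[0, 0]
        assert not ph.mask[1, 1]
        assert np.isnan(ph.re[1, 1])


class TestDenoise:
    def test_constant_field_variance_reduced_mean_kept(self):
        rng = np.random.default_rng(4)
        profile = syn.decay_profile(3.0, 128, 12.5)
        counts = rng.poisson(profile[None, None, None, :] * 800,
                             size=(1, 32, 32, 128)).astype(float)
        ph = fp.phasor_transform(make_stack(counts))
        phd = fp.denoise_phasors(ph)
        assert np.nanvar(phd.re) < 0.5 * np.nanvar(ph.re)
        assert abs(ph.photon_weighted_mean() - phd.photon_weighted_mean()) < 1e-6

    def test_noise_free_constant_unchanged(self):
        profile = syn.decay_profile(3.0, 128, 12.5)
        counts = np.tile(profile * 800, (1, 16, 16, 1))
        ph = fp.phasor_transform(make_stack(counts))
        phd = fp.denoise_phasors(ph)
        assert np.nanmax(np.abs(phd.re - ph.re)) < 1e-9

    def test_two_region_rmse_reduced(self):
        rng = np.random.default_rng(9)
        p1 = syn.decay_profile(0.9, 128, 12.5)
        p2 = syn.decay_profile(3.5, 128, 12.5)
        expected = np.empty((1, 32, 32, 128))
        expected[:, :, :16, :] = p1 * 900
        expected[:, :, 16:, :] = p2 * 900
        counts = rng.poisson(expected).astype(float)
        ph = fp.phasor_transform(make_stack(counts))
        phd = fp.denoise_phasors(ph)
        truth = np.where(
            np.arange(32)[None, :] < 16,
            fp.phasor_of_lifetime(0.9, ph.omega),
            fp.phasor_of_lifetime(3.5, ph.omega),
        )
        rmse = lambda p: np.sqrt(np.nanmean(np.abs(p.complex - truth) ** 2))
        assert rmse(phd) < rmse(ph)


class TestThreeComponentFit:
    def test_pure_inactive_pixels(self):
        model = fp.ThreeComponentModel(donor_only_fraction=0.0)
        omega = 2 * math.pi / 12.5
        r_in = fp.phasor_of_lifetime(3.5, omega)
        h, w = 4, 4
        ph = fp.PhasorImage(
            re=np.full((h, w), r_in.real),
            im=np.full((h, w), r_in.imag),
            photons=np.full((h, w), 1000.0),
            mask=np.ones((h, w), dtype=bool),
            omega=omega,
        )
        fit = fp.fit_three_components(ph, model)
        assert np.allclose(fit.photon_fractions[..., 2], 1.0, atol=1e-9)
        assert np.allclose(fit.alpha, 0.0, atol=1e-9)

    def test_infeasible_phasor_clipped(self):
        # a pixel beyond the active vertex cannot exceed f_act = 1 - f_do
        model = fp.ThreeComponentModel()
        omega = 2 * math.pi / 12.5
        r_act = fp.phasor_of_lifetime(0.9, omega)
        ph = fp.PhasorImage(
            re=np.array([[r_act.real + 0.2]]),
            im=np.array([[r_act.imag]]),
            photons=np.array([[1000.0]]),
            mask=np.array([[True]]),
            omega=omega,
        )
        fit = fp.fit_three_components(ph, model)
        assert fit.photon_fractions[0, 0, 1] == pytest.approx(0.8)
        assert fit.residual[0, 0] > 0

    def test_noise_free_alpha_recovery_exact(self):
        spec = syn.lifea2_cryo(
            seed=0, background_rate=0.0, drift_per_frame=(0.0, 0.0)
        )
        stack, truth = syn.generate_tcspc_stack(spec, noise_free=True)
        ph = fp.phasor_transform(stack)
        fit = fp.fit_three_components(ph, fp.ThreeComponentModel())
        sel = np.isfinite(truth["alpha"])
        assert np.nanmax(np.abs(fit.alpha[sel] - truth["alpha"][sel])) < 1e-3

    def test_lifetime_recovery_on_generated_data(self):
        spec = syn.lifea2_cryo(
            seed=1, background_rate=0.0, drift_per_frame=(0.0, 0.0), shape=(32, 32),
            blobs=(
                syn.Blob((10, 10), 6, 0.75, 2000.0),
                syn.Blob((22, 22), 6, 0.15, 2000.0),
            ),
        )
        stack, _ = syn.generate_tcspc_stack(spec)
        ph = fp.phasor_transform(stack)
        model = fp.ThreeComponentModel(tau_active=1.5, tau_inactive=3.0)
        fit = fp.optimize_lifetimes(ph, model)
        assert fit.tau_active == pytest.approx(0.9, abs=0.2)
        assert fit.tau_inactive == pytest.approx(3.5, abs=0.2)


class TestMolecularFractions:
    def test_hand_computed_two_state(self):
        model = fp.ThreeComponentModel(
            tau_donor_only=3.71, tau_active=1.0, tau_inactive=3.0,
            donor_only_fraction=0.0,
        )
        model.photon_fractions = np.array([[[0.0, 0.5, 0.5]]])
        out = fp.molecular_fraction_maps(model)
        # oracle: (0.5/1)/(0.5/1 + 0.5/3) = 0.75
        assert out.molecular_fractions[0, 0, 1] == pytest.approx(0.75)
        assert out.molecular_fractions[0, 0, 2] == pytest.approx(0.25)
        assert out.alpha[0, 0] == pytest.approx(0.75)

    def test_equal_lifetimes_identity(self):
        model = fp.ThreeComponentModel(
            tau_donor_only=2.0, tau_active=2.0, tau_inactive=2.0
        )
        f = np.array([[[0.2, 0.3, 0.5]]])
        model.photon_fractions = f
        out = fp.molecular_fraction_maps(model)
        assert np.allclose(out.molecular_fractions, f)

    def test_round_trip_molecular_to_photon(self):
        rng = np.random.default_rng(2)
        model = fp.ThreeComponentModel()
        f = rng.dirichlet([2, 2, 2], size=(5, 5))[None].reshape(5, 5, 3)
        model.photon_fractions = f
        out = fp.molecular_fraction_maps(model)
        back = out.molecular_fractions * out.lifetimes()[None, None, :]
        back /= back.sum(axis=2, keepdims=True)
        assert np.allclose(back, f, atol=1e-12)


class TestMapsAndFret:
    def test_average_lifetime_monoexponential(self, mono_stack):
        stack, truth, spec = mono_stack
        ph = fp.phasor_transform(stack)
        tau = fp.average_lifetime_map(ph, min_photons=100)
        sel = truth["expected_total"] > 0
        assert np.nanmean(tau[sel]) == pytest.approx(spec.tau_inactive, abs=0.01)
        assert np.isnan(tau[~sel]).all()

    def test_mixture_lifetime_between_components(self):
        p = 0.5 * syn.decay_profile(0.9, 256, 12.5) + 0.5 * syn.decay_profile(
            3.5, 256, 12.5
        )
        ph = fp.phasor_transform(make_stack(p[None, None, None, :] * 1e6))
        tau = fp.average_lifetime_map(ph)
        assert 0.9 < tau[0, 0] < 3.5

    def test_fret_efficiency_values(self):
        assert fp.fret_efficiency(0.9, 3.71) == pytest.approx(0.757, abs=1e-3)
        assert fp.fret_efficiency(3.5, 3.71) == pytest.approx(0.0566, abs=1e-3)
        assert fp.fret_efficiency(3.71, 3.71) == 0.0
        with pytest.raises(ValueError):
            fp.fret_efficiency(4.0, 3.71)


class TestPipeline:
    def test_end_to_end_products(self, cryo_scene):
        stack, truth = cryo_scene
        result = fp.run_pipeline(stack)
        assert result["model"].alpha is not None
        assert result["tau_map"].shape == truth["alpha"].shape
        assert result["dropped"] >= 0
        low = result["phasor"].photons < 50
        assert np.isnan(result["model"].alpha[low]).all()
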