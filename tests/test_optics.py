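"""Imaging model: pupil function, wave propagation, image formation,
metrics. Analytic oracles (Airy pattern, Gaussian/sinc MTFs, direct DFT
propagation) validate the FFT-based pipeline."""

import numpy as np
import pytest

from eyevo.genome import MorphologicalGene, OpticalGene
from eyevo.optics import (
    LatentScene, OpticsConfig, PupilFunction, angular_spectrum_propagate,
    build_pupil_function, compare_images, compute_cpd, compute_mtf,
    compute_psf, compute_psf_stack, delta_psf_stack, diffraction_config,
    image_quality, latent_shape, lens_phase_profile, mtf_area,
    propagate_pupil, render_retinal_image,
)


def flat_gene(a: float) -> OpticalGene:
    return OpticalGene(phase_mask=np.zeros((4, 4)), refractive_index=1.5,
                       aperture_fraction=a)


class TestPupilFunction:
    def test_zero_height_is_flat_wavefront(self):
        p = build_pupil_function(flat_gene(1.0), OpticsConfig())
        assert np.allclose(np.exp(1j * p.phase), 1.0)

    def test_index_matched_element_is_flat(self):
        og = OpticalGene(phase_mask=np.random.default_rng(0).uniform(0, 1, (4, 4)),
                         refractive_index=1.0, aperture_fraction=1.0)
        p = build_pupil_function(og, OpticsConfig())
        assert np.allclose(np.exp(1j * p.phase), 1.0)

    def test_open_eye_passes_full_circle(self):
        cfg = OpticsConfig()
        p = build_pupil_function(flat_gene(1.0), cfg)
        n = p.amplitude.shape[0]
        # inscribed circle: center row fully open, corners blocked
        assert p.amplitude[n // 2, 0] == 1.0 and p.amplitude[n // 2, -1] == 1.0
        assert p.amplitude[0, 0] == 0.0
        # fraction of the grid inside the inscribed circle ~ pi/4
        assert p.amplitude.mean() == pytest.approx(np.pi / 4, rel=0.02)

    def test_aperture_bounds_checked(self):
        with pytest.raises(ValueError):
            build_pupil_function(
                OpticalGene(aperture_fraction=1.5), OpticsConfig())


class TestPSF:
    @pytest.mark.parametrize("a", [0.05, 0.3, 1.0])
    def test_unit_sum(self, a):
        cfg = OpticsConfig()
        p = build_pupil_function(flat_gene(a), cfg)
        k = compute_psf(p, cfg, 1, 7, 7)
        assert k.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(k >= 0)

    def test_closed_pupil_is_blind(self):
        stack = compute_psf_stack(flat_gene(0.0), MorphologicalGene(), OpticsConfig())
        assert stack.blind
        assert all(k.sum() == 0 for k in stack.kernels)

    @pytest.mark.parametrize("a", [0.05, 0.1, 0.2])
    def test_airy_first_zero(self, a):
        """Flat-phase circular aperture: the first dark ring sits at
        1.22 lam s / D within one grid cell (plane-wave source,
        diffraction-scale far-field geometry). D uses the effective
        diameter of the discretely sampled pupil."""
        from scipy.signal import find_peaks

        cfg = diffraction_config()
        p = build_pupil_function(flat_gene(a), cfg, 1)
        intensity, pitch = propagate_pupil(p, cfg, 1)
        m = intensity.shape[0]
        c = (m - 1) / 2
        yy, xx = np.mgrid[0:m, 0:m]
        rbin = np.rint(np.sqrt((xx - c) ** 2 + (yy - c) ** 2)).astype(int)
        prof = np.bincount(rbin.ravel(), intensity.ravel()) \
            / np.maximum(np.bincount(rbin.ravel()), 1)
        prof = prof / prof.max()
        minima, _ = find_peaks(-prof, prominence=5e-3)
        measured = minima[0] * pitch
        r_eff = np.sqrt(p.amplitude.sum() / np.pi) * pitch
        lam = cfg.wavelengths[1]
        predicted = 1.22 * lam * cfg.focal_distance / (2 * r_eff)
        assert abs(measured - predicted) <= pitch

    def test_open_aperture_blurrier_than_pinhole(self):
        """Geometric regime: the fully open pupil smears the image, a
        near-pinhole keeps it sharp (lower vs higher MTF area)."""
        cfg = OpticsConfig()
        morph = MorphologicalGene(res_w=15, res_h=15)
        k_open = compute_psf_stack(flat_gene(1.0), morph, cfg).kernels[1]
        k_pin = compute_psf_stack(flat_gene(0.1), morph, cfg).kernels[1]
        assert mtf_area(k_open) < mtf_area(k_pin)

    def test_quadratic_lens_focuses(self):
        """An ideal-lens phase at a = 1 concentrates >= 4x more energy in
        the central 3x3 kernel cells than the flat-phase open pupil."""
        cfg = diffraction_config()
        flat = build_pupil_function(flat_gene(1.0), cfg, 1)
        lens = PupilFunction(amplitude=flat.amplitude,
                             phase=lens_phase_profile(cfg, 1),
                             pitch=flat.pitch)
        k_flat = compute_psf(flat, cfg, 1, 15, 15)
        k_lens = compute_psf(lens, cfg, 1, 15, 15)

        def central_3x3(k):
            cy, cx = k.shape[0] // 2, k.shape[1] // 2
            return k[cy - 1:cy + 2, cx - 1:cx + 2].sum()

        assert central_3x3(k_lens) >= 4 * central_3x3(k_flat)
        assert mtf_area(k_flat) < mtf_area(k_lens)

    def test_fft_matches_direct_dft_summation(self):
        """FFT propagation equals an explicit O(N^4) discrete-summation
        evaluation of the same Fresnel/angular-spectrum operator on an 8x8
        grid."""
        rng = np.random.default_rng(3)
        n, pitch, lam, dist = 8, 2e-6, 550e-9, 1e-4
        field = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        fast = angular_spectrum_propagate(field, pitch, lam, dist)

        k = 2 * np.pi / lam
        freqs = np.fft.fftfreq(n, d=pitch)
        spectrum = np.zeros((n, n), complex)
        for p in range(n):           # direct DFT, no FFT shortcuts
            for q in range(n):
                acc = 0.0 + 0.0j
                for r in range(n):
                    for c in range(n):
                        acc += field[r, c] * np.exp(
                            -2j * np.pi * (p * r + q * c) / n)
                spectrum[p, q] = acc
        out = np.zeros((n, n), complex)
        for p in range(n):
            for q in range(n):
                arg = 1 - (lam * freqs[q]) ** 2 - (lam * freqs[p]) ** 2
                h = np.exp(1j * k * dist * np.sqrt(arg)) if arg > 0 else 0.0
                spectrum[p, q] *= h
        for r in range(n):
            for c in range(n):
                acc = 0.0 + 0.0j
                for p in range(n):
                    for q in range(n):
                        acc += spectrum[p, q] * np.exp(
                            2j * np.pi * (p * r + q * c) / n)
                out[r, c] = acc / n ** 2
        assert np.max(np.abs(fast - out)) / np.max(np.abs(out)) < 1e-6


class TestImageFormation:
    def test_delta_kernel_identity(self):
        res = 5
        hp, wp = latent_shape(res, res)
        x = np.random.default_rng(0).uniform(0, 1, (hp, wp, 3))
        scene = LatentScene(image=x, depth=np.ones((hp, wp)))
        img = render_retinal_image(scene, delta_psf_stack(res, res),
                                   flat_gene(1.0),
                                   OpticsConfig(noise_sigma=0.0))
        pad = (hp - res) // 2
        assert np.allclose(img.pixels, x[pad:pad + res, pad:pad + res])

    def test_throughput_quadratic_in_aperture(self):
        res = 7
        hp, wp = latent_shape(res, res)
        x = np.random.default_rng(1).uniform(0.2, 0.8, (hp, wp, 3))
        scene = LatentScene(image=x, depth=np.ones((hp, wp)))
        cfg = OpticsConfig(noise_sigma=0.0)
        psf = delta_psf_stack(res, res)
        _, full = render_retinal_image(scene, psf, flat_gene(1.0), cfg,
                                       return_preclip=True)
        _, half = render_retinal_image(scene, psf, flat_gene(0.5), cfg,
                                       return_preclip=True)
        assert half.mean() / full.mean() == pytest.approx(0.25, abs=1e-6)

    def test_energy_conserved_on_uniform_scene(self):
        res = 9
        hp, wp = latent_shape(res, res)
        scene = LatentScene(image=np.full((hp, wp, 3), 0.6),
                            depth=np.ones((hp, wp)))
        cfg = OpticsConfig(noise_sigma=0.0)
        psf = compute_psf_stack(flat_gene(1.0), MorphologicalGene(res_w=res, res_h=res), cfg)
        img = render_retinal_image(scene, psf, flat_gene(1.0), cfg)
        assert img.pixels.mean() == pytest.approx(0.6, abs=1e-6)

    def test_padding_formula(self):
        assert latent_shape(15, 15) == (31, 31)
        assert latent_shape(1, 1) == (3, 3)
        assert latent_shape(4, 4) == (10, 10)

    def test_shape_mismatch_rejected(self):
        scene = LatentScene(image=np.zeros((5, 5, 3)), depth=np.zeros((5, 5)))
        with pytest.raises(ValueError):
            render_retinal_image(scene, delta_psf_stack(5, 5), flat_gene(1.0),
                                 OpticsConfig(noise_sigma=0.0))


class TestMTF:
    def test_delta_kernel_perfect(self):
        k = np.zeros((9, 9))
        k[4, 4] = 1.0
        _, mtf = compute_mtf(k)
        assert np.allclose(mtf, 1.0)

    def test_gaussian_width_ordering(self):
        """Closed-form oracle: MTF of an isotropic Gaussian kernel is
        Gaussian in frequency; a wider kernel lies below a narrower one at
        every nonzero frequency."""
        yy, xx = np.mgrid[-16:17, -16:17]

        def gauss(s):
            g = np.exp(-(xx**2 + yy**2) / (2 * s**2))
            return g / g.sum()

        f, narrow = compute_mtf(gauss(1.0), n_bins=16)
        _, wide = compute_mtf(gauss(3.0), n_bins=16)
        assert np.all(wide[1:] <= narrow[1:] + 1e-12)
        # closed-form continuous-FT oracle, evaluated at annulus centers
        # (radial binning averages over |f| within each annulus, so the
        # comparison is moderately toleranced)
        oracle = np.exp(-2 * (np.pi * 3.0 * f * 0.5) ** 2)
        assert np.allclose(wide[1:8], oracle[1:8], atol=0.06)

    def test_flat_kernel_sinc_null(self):
        """A 1-D uniform kernel's MTF is |sinc|, vanishing at 1/width."""
        width = 8
        k = np.ones((1, width)) / width
        f, mtf = compute_mtf(k, n_bins=width * 8)
        # first sinc null at f = 1/width cycles/sample = 0.25 Nyquist units
        null = 2.0 / width
        region = (f > null * 0.85) & (f < null * 1.15)
        assert mtf[region].min() < 0.05
        assert mtf[f < null * 0.5].min() > 0.2


class TestImageQuality:
    def test_delta_open_is_maximal(self):
        assert image_quality(delta_psf_stack(7, 7), flat_gene(1.0)) == \
            pytest.approx(1.0)

    def test_aperture_squared_factor(self):
        q = image_quality(delta_psf_stack(7, 7), flat_gene(0.1))
        assert q == pytest.approx(0.01)

    def test_lens_beats_pinhole_and_open(self):
        """Sharp optics at full aperture dominates both the pinhole
        (sharp, dim) and the unlensed open eye (bright, blurry)."""
        cfg = OpticsConfig()
        morph = MorphologicalGene(res_w=15, res_h=15)
        open_blurry = compute_psf_stack(flat_gene(1.0), morph, cfg)
        pinhole = compute_psf_stack(flat_gene(0.1), morph, cfg)
        q_lens = image_quality(delta_psf_stack(15, 15), flat_gene(1.0))
        q_pin = image_quality(pinhole, flat_gene(0.1))
        q_open = image_quality(open_blurry, flat_gene(1.0))
        assert q_lens > q_pin
        assert q_lens > q_open


class TestCPD:
    def test_nyquist_formula(self):
        assert compute_cpd(MorphologicalGene(res_w=15, fov_deg=45.0)) == \
            pytest.approx(15 / 90.0)
        assert compute_cpd(MorphologicalGene(res_w=1, fov_deg=45.0)) == \
            pytest.approx(1 / 90.0)

    def test_linear_in_resolution(self):
        one = compute_cpd(MorphologicalGene(res_w=4, fov_deg=60.0))
        two = compute_cpd(MorphologicalGene(res_w=8, fov_deg=60.0))
        assert two == pytest.approx(2 * one)


class TestCompareImages:
    def test_identical_images(self):
        x = np.random.default_rng(0).uniform(0, 1, (16, 16, 3))
        psnr, ssim = compare_images(x, x)
        assert np.isinf(psnr)
        assert ssim == pytest.approx(1.0)

    def test_uniform_offset_psnr(self):
        x = np.full((32, 32), 0.4)
        psnr, _ = compare_images(x, x + 0.1)
        assert psnr == pytest.approx(20.0, abs=1e-9)

    def test_ssim_noise_monotonicity(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.2, 0.8, (32, 32))
        noisy_small = np.clip(x + rng.normal(0, 0.02, x.shape), 0, 1)
        noisy_big = np.clip(x + rng.normal(0, 0.2, x.shape), 0, 1)
        _, s_small = compare_images(x, noisy_small)
        _, s_big = compare_images(x, noisy_big)
        assert s_big < s_small

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            compare_images(np.zeros((4, 4)), np.zeros((5, 5)))
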