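import numpy as np
import pytest

from spirct.decompose import (
    MetalPrior,
    SpectralModel,
    decompose_ray,
    decompose_sinogram,
    extract_metal_prior,
    neg_log_likelihood,
    pseudo_mono_sinogram,
)
from spirct.phantom import MaterialMap
from spirct.physics import gold_attenuation_basis
from spirct.projector import get_projector, simulate_acquisition
from spirct.spectrum import default_spectrum, make_bin_scheme


@pytest.fixture(scope="module")
def model(spectrum_module, bins_module):
    spec = spectrum_module.normalized(1e5)
    return SpectralModel(spec, bins_module)


@pytest.fixture(scope="module")
def spectrum_module():
    return default_spectrum()


@pytest.fixture(scope="module")
def bins_module(spectrum_module):
    return make_bin_scheme(spectrum=spectrum_module)


class TestNegLogLikelihood:
    def test_stationary_at_truth_noiseless(self, model):
        a = np.array([4e4, 1.5, 0.3])
        counts = model.expected_counts(a)
        eps = np.array([1e-2, 1e-6, 1e-6])
        for j in range(3):
            step = np.zeros(3)
            step[j] = eps[j]
            plus = neg_log_likelihood(a + step, counts, model)
            minus = neg_log_likelihood(a - step, counts, model)
            deriv = (plus - minus) / (2 * eps[j])
            scale = abs(neg_log_likelihood(a, counts, model)) + 1.0
            assert abs(deriv) * eps[j] < 1e-6 * scale

    def test_empty_beam_plugin_value(self, model):
        incident = model.incident
        expected = float(np.sum(incident - incident * np.log(incident)))
        assert neg_log_likelihood(np.zeros(3), incident, model) == pytest.approx(
            expected, rel=1e-12
        )

    def test_matches_independent_quadrature(self, model):
        """Re-evaluate the likelihood with an explicit loop oracle."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.random(3) * np.array([1e5, 3.0, 2.0])
            counts = rng.poisson(np.maximum(model.expected_counts(a), 0.01))
            oracle = 0.0
            for n in range(model.n_bins):
                lam = 0.0
                for k in range(model.spectrum.energies.size):
                    if model.window[n, k]:
                        depth = (
                            a[0] * model.basis.f_pe[k]
                            + a[1] * model.basis.f_kn[k]
                            + a[2] * model.basis.f_au[k]
                        )
                        lam += model.fluence[k] * np.exp(-depth)
                lam = max(lam, 1e-12)
                oracle += lam - (counts[n] * np.log(lam) if counts[n] > 0 else 0.0)
            assert neg_log_likelihood(a, counts, model) == pytest.approx(oracle, rel=1e-10)

    def test_rejects_negative_counts(self, model):
        with pytest.raises(ValueError):
            neg_log_likelihood(np.zeros(3), np.array([-1.0, 0, 0, 0, 0, 0]), model)


class TestDecomposeRay:
    def test_pure_gold_round_trip(self, model):
        truth = np.array([0.0, 0.0, 1.93])  # 0.1 cm of pure gold
        counts = model.expected_counts(truth)
        a, nll, ok = decompose_ray(counts, model)
        assert ok
        assert a[2] == pytest.approx(1.93, rel=1e-3)

    def test_empty_beam_recovers_air(self, model):
        a, _, _ = decompose_ray(model.incident, model)
        assert np.all(np.abs(a * model.scale) < 1e-3)

    def test_matches_grid_search_oracle(self, model):
        """Nelder-Mead lands on the coarse-grid + polish minimum."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            truth = rng.random(3) * np.array([5e4, 2.0, 1.0])
            counts = model.expected_counts(truth)
            a, nll, _ = decompose_ray(counts, model)
            # 21^3 grid around truth, then polish from the best node
            grids = [np.linspace(0.5 * t, 1.5 * t + 1e-6, 21) for t in truth]
            best, best_val = None, np.inf
            for g0 in grids[0]:
                for g1 in grids[1]:
                    for g2 in grids[2]:
                        val = neg_log_likelihood([g0, g1, g2], counts, model)
                        if val < best_val:
                            best, best_val = np.array([g0, g1, g2]), val
            polished, pol_val, _ = decompose_ray(counts, model, init=best)
            assert nll <= pol_val + 1e-6 * abs(pol_val)
            assert np.allclose(a, polished, rtol=5e-3, atol=1e-3)

    def test_requires_three_windows(self, model):
        with pytest.raises(ValueError):
            decompose_ray(np.array([1.0, 2.0]), model)


@pytest.fixture(scope="module")
def noiseless_run(small_phantom, small_phantom_geometry, spectrum_module, bins_module):
    spectral = simulate_acquisition(
        small_phantom, spectrum_module, bins_module, small_phantom_geometry,
        photon_budget=1e5, noiseless=True,
    )
    model = SpectralModel.from_sinogram(spectral, spectrum_module)
    basis = decompose_sinogram(spectral, model)
    proj = get_projector(
        small_phantom_geometry, small_phantom.shape[0], small_phantom.pixel_size
    )
    truth = np.stack(
        [proj.fp(small_phantom.a1), proj.fp(small_phantom.a2), proj.fp(small_phantom.a3)],
        axis=-1,
    )
    return basis, truth, spectral


class TestDecomposeSinogram:
    def test_empty_sinogram_decomposes_to_zero(
        self, small_phantom_geometry, spectrum_module, bins_module, small_phantom
    ):
        n = small_phantom.shape[0]
        z = np.zeros((n, n))
        empty = MaterialMap(z.copy(), z.copy(), z.copy(), small_phantom.pixel_size)
        spectral = simulate_acquisition(
            empty, spectrum_module, bins_module, small_phantom_geometry,
            photon_budget=1e5, noiseless=True,
        )
        model = SpectralModel.from_sinogram(spectral, spectrum_module)
        basis = decompose_sinogram(spectral, model)
        assert np.abs(basis.lines).max() < 1e-4

    def test_gold_support(self, noiseless_run):
        basis, truth, _ = noiseless_run
        off_gold = truth[..., 2] == 0.0
        assert basis.a3_line[off_gold].max() < 1e-3 * basis.a3_line.max()

    def test_noiseless_round_trip_on_measured_rays(self, noiseless_run):
        """Line integrals recover to 0.1% where every window has photons."""
        basis, truth, spectral = noiseless_run
        measured = (spectral.counts >= 10).all(axis=2) & (truth[..., 1] > 0.05)
        for j in range(3):
            t = truth[..., j][measured]
            e = basis.lines[..., j][measured]
            denom = np.maximum(np.abs(t), 1e-3 * np.abs(t).max() + 1e-12)
            assert (np.abs(e - t) / denom).max() < 1e-3

    def test_deterministic(self, noiseless_run, spectrum_module):
        basis, _, spectral = noiseless_run
        model = SpectralModel.from_sinogram(spectral, spectrum_module)
        again = decompose_sinogram(spectral, model)
        assert np.array_equal(basis.a3_line, again.a3_line)


class TestPseudoMono:
    def _basis(self, small_phantom_geometry, a3_value=0.0):
        nv, nd = small_phantom_geometry.n_views, small_phantom_geometry.n_detector
        zeros = np.zeros((nv, nd))
        from spirct.decompose import BasisSinogram

        return BasisSinogram(
            a1_line=zeros.copy(), a2_line=zeros.copy(),
            a3_line=np.full((nv, nd), a3_value),
            geometry=small_phantom_geometry,
            converged=np.ones((nv, nd), dtype=bool),
            negloglik=zeros.copy(),
        )

    def test_zero_basis_gives_source_intensity(self, small_phantom_geometry):
        sino = pseudo_mono_sinogram(self._basis(small_phantom_geometry), 55.0, 1e4)
        assert np.all(sino.values == 1e4)
        assert sino.domain == "counts"

    def test_pure_gold_line_integral(self, small_phantom_geometry):
        sino = pseudo_mono_sinogram(self._basis(small_phantom_geometry, 1.93), 55.0, 1e4)
        expected = 1e4 * np.exp(-1.93 * gold_attenuation_basis(55.0))
        assert np.allclose(sino.values, expected, rtol=1e-12)

    def test_monotone_in_line_integrals(self, small_phantom_geometry):
        lo = pseudo_mono_sinogram(self._basis(small_phantom_geometry, 0.5), 55.0, 1e4)
        hi = pseudo_mono_sinogram(self._basis(small_phantom_geometry, 0.6), 55.0, 1e4)
        assert np.all(hi.values < lo.values)


class TestExtractMetalPrior:
    def test_no_gold_channel_is_empty_prior(self, small_phantom_geometry, small_phantom):
        from spirct.decompose import BasisSinogram

        nv, nd = small_phantom_geometry.n_views, small_phantom_geometry.n_detector
        zeros = np.zeros((nv, nd))
        basis = BasisSinogram(
            zeros.copy(), zeros.copy(), zeros.copy(), small_phantom_geometry,
            np.ones((nv, nd), dtype=bool), zeros.copy(),
        )
        prior = extract_metal_prior(basis, small_phantom_geometry, 128, 0.1)
        assert prior.is_empty

    def test_threshold_invariant_to_rescaling(
        self, small_phantom, small_phantom_geometry, spectrum_module, bins_module
    ):
        spectral = simulate_acquisition(
            small_phantom, spectrum_module, bins_module, small_phantom_geometry,
            photon_budget=1e5, noiseless=True,
        )
        model = SpectralModel.from_sinogram(spectral, spectrum_module)
        basis = decompose_sinogram(spectral, model)
        prior = extract_metal_prior(
            basis, small_phantom_geometry, 128, 0.1, refit_density=False
        )
        basis.a3_line *= 7.5
        scaled = extract_metal_prior(
            basis, small_phantom_geometry, 128, 0.1, refit_density=False
        )
        assert np.array_equal(prior.mask, scaled.mask)

    def test_threshold_zeroes_low_pixels(
        self, small_phantom, small_phantom_geometry, spectrum_module, bins_module
    ):
        spectral = simulate_acquisition(
            small_phantom, spectrum_module, bins_module, small_phantom_geometry,
            photon_budget=1e5, noiseless=True,
        )
        model = SpectralModel.from_sinogram(spectral, spectrum_module)
        basis = decompose_sinogram(spectral, model)
        prior = extract_metal_prior(
            basis, small_phantom_geometry, 128, 0.1, refit_density=False
        )
        nz = prior.density_image[prior.mask]
        assert nz.min() >= 0.1 * prior.density_image.max()


class TestMetalPriorPerturbation:
    def test_perturbed_prior_density_filled(self):
        density = np.zeros((32, 32))
        density[14:18, 14:18] = 19.0
        prior = MetalPrior(density, density > 0)
        grown = prior.perturbed(1)
        assert grown.mask.sum() > prior.mask.sum()
        new = grown.mask & ~prior.mask
        assert np.allclose(grown.density_image[new], 19.0)
        shrunk = prior.perturbed(-1)
        assert shrunk.mask.sum() < prior.mask.sum()
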