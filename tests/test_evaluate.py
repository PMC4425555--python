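import numpy as np
import pytest
import scipy.ndimage as ndi

from spirct.decompose import MetalPrior
from spirct.evaluate import (
    LineSpec,
    artifact_index,
    boundary_distances,
    compare_masks,
    density_error,
    line_profile,
    profile_rmse,
)
from spirct.phantom import PhantomSpec, build_jaw_phantom
from spirct.physics import gold_attenuation_basis
from spirct.recon import ReconImage


@pytest.fixture(scope="module")
def phantom():
    return build_jaw_phantom(PhantomSpec(grid_size=128, pixel_size=0.1))


@pytest.fixture(scope="module")
def implant_column(phantom):
    rows, cols = np.nonzero(phantom.metal_mask)
    return int(round(cols.mean()))


class TestLineProfile:
    def test_constant_image(self, phantom, implant_column):
        image = np.full(phantom.shape, 0.25)
        report = line_profile(image, LineSpec(index=implant_column), phantom)
        assert np.all(report.values["image"] == 0.25)

    def test_length_matches_line(self, phantom):
        report = line_profile(np.zeros(phantom.shape), LineSpec(index=5, start=10, stop=50), phantom)
        assert report.positions.size == 40

    def test_reference_contains_gold_value(self, phantom, implant_column):
        truth_mu = phantom.attenuation_image(55.0)
        report = line_profile(truth_mu, LineSpec(index=implant_column), phantom)
        gold_mu = 19.3 * gold_attenuation_basis(55.0)
        assert report.reference.max() == pytest.approx(gold_mu, rel=1e-6)

    def test_out_of_bounds_rejected(self, phantom):
        with pytest.raises(ValueError):
            line_profile(np.zeros(phantom.shape), LineSpec(index=500), phantom)


class TestProfileRMSE:
    def test_zero_when_equal(self, phantom, implant_column):
        truth_mu = phantom.attenuation_image(55.0)
        report = line_profile(truth_mu, LineSpec(index=implant_column), phantom)
        assert profile_rmse(report, "image") == 0.0

    def test_constant_shift(self, phantom, implant_column):
        truth_mu = phantom.attenuation_image(55.0)
        report = line_profile(truth_mu + 0.03, LineSpec(index=implant_column), phantom)
        assert profile_rmse(report, "image") == pytest.approx(0.03, rel=1e-9)

    def test_metal_exclusion_matters(self, phantom, implant_column):
        truth_mu = phantom.attenuation_image(55.0)
        wrong_metal = truth_mu.copy()
        wrong_metal[phantom.metal_mask] = 0.0
        report = line_profile(wrong_metal, LineSpec(index=implant_column), phantom)
        assert profile_rmse(report, "image") == 0.0
        assert profile_rmse(report, "image", include_metal=True) > 1.0


class TestCompareMasks:
    def _prior(self, mask, density=19.3):
        return MetalPrior(np.where(mask, density, 0.0), mask)

    def test_identical_masks(self, phantom):
        truth = phantom.metal_mask
        report = compare_masks(self._prior(truth), truth)
        assert report.mask_boundary_distance_max == 0.0
        assert report.xor_pixels == 0
        assert report.mean_density_error_pct == pytest.approx(0.0)

    def test_dilated_by_one_pixel(self, phantom):
        truth = phantom.metal_mask
        grown = ndi.binary_dilation(truth, ndi.generate_binary_structure(2, 1))
        report = compare_masks(self._prior(grown), truth)
        assert report.mask_boundary_distance_max == pytest.approx(1.0)

    def test_empty_decomposed_mask_flags_infinity(self, phantom):
        truth = phantom.metal_mask
        empty = np.zeros_like(truth)
        report = compare_masks(self._prior(empty), truth)
        assert report.infinite_distance

    def test_percent_and_absolute_errors_consistent(self, phantom):
        truth = phantom.metal_mask
        report = compare_masks(self._prior(truth, density=18.0), truth)
        assert report.mean_density_error_pct == pytest.approx(
            100.0 * report.mean_density_error_abs / 19.3, rel=1e-12
        )
        assert report.mean_density_error_abs == pytest.approx(1.3, rel=1e-9)


def test_boundary_distance_symmetry(phantom):
    truth = phantom.metal_mask
    grown = ndi.binary_dilation(truth)
    assert boundary_distances(truth, grown) == boundary_distances(grown, truth)


def test_density_error_empty_mask():
    pct, ab = density_error(np.zeros((8, 8)), 19.3, np.zeros((8, 8), dtype=bool))
    assert np.isnan(pct) and np.isnan(ab)


class TestArtifactIndex:
    def test_truth_image_scores_zero(self, phantom):
        truth_mu = np.clip(phantom.attenuation_image(55.0), 0, None)
        image = ReconImage(truth_mu, phantom.pixel_size)
        assert artifact_index(image, phantom) == pytest.approx(0.0, abs=1e-9)

    def test_shading_increases_index(self, phantom):
        truth_mu = np.clip(phantom.attenuation_image(55.0), 0, None)
        shaded = truth_mu.copy()
        ring = ndi.binary_dilation(phantom.metal_mask, iterations=5) & ~phantom.metal_mask
        shaded[ring] += 0.05
        assert artifact_index(ReconImage(shaded, 0.1), phantom) > artifact_index(
            ReconImage(truth_mu, 0.1), phantom
        )

    def test_requires_implant(self):
        empty = build_jaw_phantom(PhantomSpec(grid_size=128, pixel_size=0.1, implant_shape="none"))
        with pytest.raises(ValueError):
            artifact_index(ReconImage(np.zeros((128, 128)), 0.1), empty)
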