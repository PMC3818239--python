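import math

import numpy as np
import pytest

from scopeqc.beads import (
    MultipleBeadsError,
    bead_centroids,
    psf_metrics,
)
from scopeqc.fixtures import generate_fixture
from scopeqc.profiles import FWHM_FACTOR

from conftest import make_stack


class TestBeadCentroids:
    def test_identical_channels_zero_distance(self):
        stack, _ = generate_fixture("bead")
        result = bead_centroids(stack)
        assert not result.absent
        np.testing.assert_allclose(result.xy_distance, 0.0, atol=1e-12)
        np.testing.assert_allclose(result.z_distance, 0.0, atol=1e-12)

    def test_known_offsets_recovered(self):
        stack, truth = generate_fixture(
            "bead", dict(offsets_um=((0.0, 0.0, 0.0), (0.20, -0.10, 0.45),
                                     (0.0, 0.0, 0.0), (0.0, 0.0, 0.0))))
        result = bead_centroids(stack)
        half_xy = truth.parameters["voxel_um"][0] / 2
        half_z = truth.parameters["voxel_um"][2] / 2
        assert result.xy_distance[0, 1] == pytest.approx(
            math.hypot(0.20, -0.10), abs=half_xy)
        assert result.z_distance[0, 1] == pytest.approx(0.45, abs=half_z)

    def test_two_beads_rejected(self):
        stack, _ = generate_fixture("bead", dict(
            n_beads=2, shape=(15, 96, 96),
            second_bead_offset_um=(1.0, 1.0, 0.0)))
        with pytest.raises(MultipleBeadsError, match="2"):
            bead_centroids(stack)

    def test_distance_matrices_symmetric(self):
        stack, _ = generate_fixture(
            "bead", dict(offsets_um=((0, 0, 0), (0.1, 0, 0.15),
                                     (0, 0.1, 0), (0.05, 0.05, 0.3)),
                         read_noise_sd=5.0))
        result = bead_centroids(stack)
        np.testing.assert_allclose(result.xy_distance, result.xy_distance.T)
        np.testing.assert_allclose(result.z_distance, result.z_distance.T)
        np.testing.assert_allclose(np.diag(result.xy_distance), 0.0)

    def test_channel_relabelling_permutes_distances(self):
        offsets = ((0, 0, 0), (0.12, -0.06, 0.15), (0.06, 0.06, 0.3),
                   (-0.06, 0.0, 0.0))
        stack, _ = generate_fixture("bead", dict(offsets_um=offsets))
        result = bead_centroids(stack)
        perm = [2, 0, 3, 1]
        permuted_offsets = tuple(offsets[i] for i in perm)
        stack_p, _ = generate_fixture("bead",
                                      dict(offsets_um=permuted_offsets))
        result_p = bead_centroids(stack_p)
        for a in range(4):
            for b in range(4):
                assert result_p.xy_distance[a, b] == pytest.approx(
                    result.xy_distance[perm[a], perm[b]], abs=1e-9)

    def test_centroid_equivariant_under_integer_voxel_shift(self):
        stack, _ = generate_fixture("bead", dict(
            wavelengths_nm=(488.0, 561.0),
            offsets_um=((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))))
        base = bead_centroids(stack)
        shift = (2, 3, 1)  # (z, y, x) voxels
        shifted_pixels = np.roll(stack.pixels, shift, axis=(2, 3, 4))
        stack_s = make_stack(shifted_pixels,
                             pixel_size_xy=stack.pixel_size_xy,
                             z_step=stack.z_step,
                             channel_wavelengths=stack.channel_wavelengths)
        moved = bead_centroids(stack_s)
        dx = shift[2] * stack.pixel_size_xy
        dy = shift[1] * stack.pixel_size_xy
        dz = shift[0] * stack.z_step
        for rec0, rec1 in zip(base.records, moved.records):
            assert rec1.centroid[0] == pytest.approx(rec0.centroid[0] + dx,
                                                     abs=1e-9)
            assert rec1.centroid[1] == pytest.approx(rec0.centroid[1] + dy,
                                                     abs=1e-9)
            assert rec1.centroid[2] == pytest.approx(rec0.centroid[2] + dz,
                                                     abs=1e-9)

    def test_z_step_refinement_convergence(self):
        coarse, _ = generate_fixture("bead", dict(
            wavelengths_nm=(488.0, 561.0),
            offsets_um=((0.0, 0.0, 0.0), (0.0, 0.0, 0.2)),
            voxel_um=(0.03, 0.03, 0.15), shape=(21, 48, 48)))
        fine, _ = generate_fixture("bead", dict(
            wavelengths_nm=(488.0, 561.0),
            offsets_um=((0.0, 0.0, 0.0), (0.0, 0.0, 0.2)),
            voxel_um=(0.03, 0.03, 0.075), shape=(41, 48, 48)))
        d_coarse = bead_centroids(coarse).z_distance[0, 1]
        d_fine = bead_centroids(fine).z_distance[0, 1]
        assert abs(d_fine - d_coarse) < 0.15  # less than one coarse z-step

    def test_empty_channel_flagged_absent(self):
        stack, _ = generate_fixture("bead", dict(
            wavelengths_nm=(488.0, 561.0),
            offsets_um=((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))))
        pixels = stack.pixels.copy()
        pixels[0, 1] = 0
        stack.pixels = pixels
        result = bead_centroids(stack)
        assert result.absent == [1]
        assert result.records[1] is None
        assert np.isnan(result.xy_distance[0, 1])

    def test_single_channel_rejected(self):
        stack, _ = generate_fixture("psf")
        with pytest.raises(ValueError, match="2 channels"):
            bead_centroids(stack)

    def test_threshold_is_half_filtered_max(self):
        stack, _ = generate_fixture("bead", dict(
            wavelengths_nm=(488.0, 561.0),
            offsets_um=((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))))
        result = bead_centroids(stack)
        for rec in result.records:
            assert rec.threshold_value > 0
            assert rec.voxel_count >= 1


class TestPsfMetrics:
    def test_noiseless_closed_form(self):
        stack, _ = generate_fixture("psf", dict(sigma_um=(0.1, 0.1, 0.3)))
        result = psf_metrics(stack)
        assert result.lateral_fwhm_x == pytest.approx(FWHM_FACTOR * 0.1,
                                                      rel=0.02)
        assert result.lateral_fwhm_y == pytest.approx(FWHM_FACTOR * 0.1,
                                                      rel=0.02)
        assert result.axial_fwhm == pytest.approx(FWHM_FACTOR * 0.3,
                                                  rel=0.02)
        assert not result.fallback_axes

    def test_isotropic_fixture_symmetry(self):
        stack, _ = generate_fixture("psf", dict(sigma_um=(0.12, 0.12, 0.12),
                                                voxel_um=(0.03, 0.03, 0.03),
                                                shape=(48, 48, 48)))
        result = psf_metrics(stack)
        assert result.lateral_fwhm_x == pytest.approx(result.lateral_fwhm_y,
                                                      rel=1e-6)

    def test_axial_at_least_lateral_on_confocal_fixture(self):
        stack, _ = generate_fixture("psf")
        result = psf_metrics(stack)
        assert result.axial_fwhm >= min(result.lateral_fwhm_x,
                                        result.lateral_fwhm_y)

    def test_noisy_mean_bias_small(self):
        truth = FWHM_FACTOR * 0.1
        values = []
        for seed in range(8):
            stack, _ = generate_fixture("psf", dict(read_noise_sd=40.0),
                                        seed=seed)
            values.append(psf_metrics(stack).lateral_fwhm_x)
        assert abs(np.mean(values) - truth) / truth < 0.05

    def test_multichannel_rejected(self):
        stack, _ = generate_fixture("bead")
        with pytest.raises(ValueError, match="single channel"):
            psf_metrics(stack)

    def test_empty_stack_rejected(self):
        stack = make_stack(np.zeros((1, 1, 9, 32, 32), dtype=np.uint16),
                           pixel_size_xy=0.03, z_step=0.15)
        with pytest.raises(ValueError, match="no bead"):
            psf_metrics(stack)
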