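import numpy as np
import pytest
from oracles import (brute_detect_maxima, brute_gaussian_gradient,
                     flood_fill_components, literal_axial_resultant)

from mtjquant.synthetic_data import generate_isotropic_micrograph
from mtjquant.wtmm2d import (DEFAULT_SCALES_UM, AnisotropyProfile,
                             MaximaSet, MicrographImage,
                             UndefinedAnisotropyError, anisotropy_factor,
                             chain_maxima, compare_anisotropy,
                             detect_modulus_maxima,
                             gaussian_gradient_transform,
                             multiscale_anisotropy)


def make_maxima(arguments):
    arguments = np.asarray(arguments, dtype=float)
    n = arguments.size
    return MaximaSet(2.0, (64, 64), np.zeros(n, int), np.arange(n),
                     np.ones(n), arguments)


class TestTransform:
    def test_constant_image_has_zero_modulus(self):
        img = MicrographImage(np.full((32, 32), 7.0), 1.0)
        field = gaussian_gradient_transform(img, 2.5)
        assert np.allclose(field.modulus, 0.0, atol=1e-12)
        assert detect_modulus_maxima(field).n_maxima == 0

    def test_vertical_step_edge_orientation(self):
        px = np.zeros((64, 64))
        px[:, 32:] = 1.0
        field = gaussian_gradient_transform(MicrographImage(px, 1.0), 2.0)
        mid = slice(16, 48)
        # gradient points +x along the edge; modulus peaks on the edge column
        assert np.allclose(field.argument[mid, 31], 0.0, atol=1e-6)
        assert np.all(field.modulus[32, :].argmax() in (31, 32))

    def test_matches_brute_force_convolution(self, rng):
        for _ in range(3):
            px = rng.uniform(0, 100, (16, 16))
            field = gaussian_gradient_transform(
                MicrographImage(px, 1.0), 2.0)
            bgx, bgy = brute_gaussian_gradient(px, 2.0)
            scale = np.abs(bgx).max()
            assert np.abs(field.gx - bgx).max() / scale < 1e-8
            assert np.abs(field.gy - bgy).max() / scale < 1e-8

    def test_unresolvable_scale_errors(self):
        img = MicrographImage(np.zeros((32, 32)), 1.0)
        with pytest.raises(ValueError, match="resolvable"):
            gaussian_gradient_transform(img, 1.5)

    def test_nonfinite_pixels_rejected(self):
        px = np.ones((32, 32))
        px[3, 3] = np.nan
        with pytest.raises(ValueError):
            MicrographImage(px, 1.0)


class TestMaxima:
    def test_straight_edge_gives_one_collinear_chain(self):
        px = np.zeros((48, 48))
        px[:, 24:] = 100.0
        field = gaussian_gradient_transform(MicrographImage(px, 1.0), 2.0)
        mx = chain_maxima(detect_modulus_maxima(field))
        assert mx.n_maxima > 0
        assert len(np.unique(mx.cols)) == 1          # collinear
        assert len(mx.chains) == 1                   # one chain
        assert np.ptp(np.mod(mx.argument, np.pi)) < 1e-6  # constant axis

    def test_disk_rim_maxima_point_radially(self):
        """Maxima of a bright disk sit near the rim with arguments equal
        to the polar angle ± π (inward gradient) within 5°."""
        h = w = 96
        yy, xx = np.mgrid[0:h, 0:w]
        cy = cx = (h - 1) / 2
        r = np.hypot(yy - cy, xx - cx)
        px = np.where(r <= 28.0, 1000.0, 0.0)
        field = gaussian_gradient_transform(MicrographImage(px, 1.0), 2.0)
        mx = detect_modulus_maxima(field, 0.8)
        assert mx.n_maxima > 40
        rim_r = np.hypot(mx.rows - cy, mx.cols - cx)
        assert np.all(np.abs(rim_r - 28.0) < 3.0)
        polar = np.arctan2(mx.rows - cy, mx.cols - cx)
        dev = np.angle(np.exp(1j * (mx.argument - (polar + np.pi))))
        assert np.degrees(np.sqrt(np.mean(dev**2))) < 5.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(3):
            px = rng.uniform(0, 50, (24, 24))
            field = gaussian_gradient_transform(MicrographImage(px, 1.0), 2.0)
            mx = detect_modulus_maxima(field, 0.5)
            expected = brute_detect_maxima(field.modulus, field.argument,
                                           field.sigma_px, 0.5)
            assert sorted(zip(mx.rows, mx.cols)) == sorted(expected)


class TestChains:
    def as_maxima(self, coords):
        coords = np.asarray(coords)
        return MaximaSet(2.0, (20, 20), coords[:, 0], coords[:, 1],
                         np.ones(len(coords)), np.zeros(len(coords)))

    def test_chebyshev_distance_one_joins(self):
        mx = chain_maxima(self.as_maxima([[5, 5], [6, 6]]))
        assert len(mx.chains) == 1

    def test_chebyshev_distance_two_splits(self):
        mx = chain_maxima(self.as_maxima([[5, 5], [7, 7]]))
        assert len(mx.chains) == 2

    def test_chains_partition_points(self, rng):
        coords = np.unique(rng.integers(0, 20, (60, 2)), axis=0)
        mx = chain_maxima(self.as_maxima(coords))
        covered = np.concatenate(mx.chains)
        assert sorted(covered) == list(range(mx.n_maxima))

    def test_count_matches_flood_fill(self, rng):
        mask = rng.uniform(size=(20, 20)) < 0.25
        coords = np.argwhere(mask)
        if len(coords) == 0:
            pytest.skip("empty draw")
        mx = chain_maxima(self.as_maxima(coords))
        assert len(mx.chains) == flood_fill_components(mask)


class TestAnisotropyFactor:
    def test_identical_arguments(self):
        assert anisotropy_factor(make_maxima(np.full(50, 0.7))) == \
            pytest.approx(1.0)

    def test_antiparallel_arguments_agree_axially(self):
        args = np.array([0.0] * 25 + [np.pi] * 25)
        assert anisotropy_factor(make_maxima(args)) == pytest.approx(1.0)

    def test_four_quadrants_cancel(self):
        args = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2] * 10)
        assert anisotropy_factor(make_maxima(args)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_uniform_arguments_obey_rayleigh_bound(self, rng):
        args = rng.uniform(-np.pi, np.pi, 10_000)
        assert anisotropy_factor(make_maxima(args)) < 0.03

    def test_matches_literal_vector_sum(self, rng):
        args = rng.uniform(-np.pi, np.pi, 257)
        mx = make_maxima(args)
        assert anisotropy_factor(mx) == \
            pytest.approx(literal_axial_resultant(args), abs=1e-12)

    def test_empty_set_is_flagged_not_zero(self):
        with pytest.raises(UndefinedAnisotropyError):
            anisotropy_factor(make_maxima([]))


class TestMultiscale:
    def test_default_grid_spans_paper_range(self):
        assert DEFAULT_SCALES_UM[0] == pytest.approx(1.88)
        assert DEFAULT_SCALES_UM[-1] == pytest.approx(4.02)
        assert len(DEFAULT_SCALES_UM) >= 7
        ratios = DEFAULT_SCALES_UM[1:] / DEFAULT_SCALES_UM[:-1]
        assert np.allclose(ratios, ratios[0])  # logarithmic spacing

    def test_parallel_stripes_highly_anisotropic(self):
        """Noiseless parallel stripes give F >= 0.95 at every scale below
        half the stripe spacing."""
        px_um = 0.3
        spacing = 12.0
        x = (np.arange(256) + 0.5) * px_um
        img = np.tile(500.0 * (1 + np.cos(2 * np.pi * x / spacing)), (256, 1))
        profile = multiscale_anisotropy(
            MicrographImage(img, px_um, "stripes"))
        below = profile.scales_um < spacing / 2
        assert below.all()
        assert np.all(profile.F[below] >= 0.95)

    def test_isotropic_noise_low_anisotropy(self):
        image = generate_isotropic_micrograph((512, 512), 0.3, 20.0, seed=2)
        profile = multiscale_anisotropy(image)
        strong = profile.n_maxima >= 200
        assert strong.any()
        assert np.all(profile.F[strong] < 0.2)

    def test_intensity_invariance(self, organized_scene):
        _, image, _ = organized_scene
        base = multiscale_anisotropy(image)
        scaled = MicrographImage(2.5 * image.pixels + 40.0,
                                 image.pixel_size, "affine")
        other = multiscale_anisotropy(scaled)
        assert np.abs(base.F - other.F).max() < 1e-9
        assert np.array_equal(base.n_maxima, other.n_maxima)

    def test_rotation_covariance(self, organized_scene):
        _, image, _ = organized_scene
        base = multiscale_anisotropy(image)
        rot = MicrographImage(np.rot90(image.pixels).copy(),
                              image.pixel_size, "rot90")
        other = multiscale_anisotropy(rot)
        assert np.abs(base.F - other.F).max() < 0.02

    def test_f_bounded(self, organized_scene):
        _, image, _ = organized_scene
        profile = multiscale_anisotropy(image)
        assert np.all((profile.F >= 0) & (profile.F <= 1))

    def test_scale_error_annotated(self):
        img = MicrographImage(np.random.default_rng(0).uniform(0, 1, (32, 32)),
                              0.3)
        with pytest.raises(ValueError, match="scale 0.1"):
            multiscale_anisotropy(img, [0.1, 2.0])


class TestCompareAnisotropy:
    def profile(self, F, image_id="p"):
        F = np.asarray(F, dtype=float)
        scales = np.geomspace(1.88, 4.02, F.size)
        return AnisotropyProfile(image_id, scales, F,
                                 np.full(F.size, 100, dtype=int))

    def test_identical_groups_null(self):
        group = [self.profile([0.4, 0.5, 0.6]) for _ in range(4)]
        table = compare_anisotropy(group, group)
        assert np.allclose(table["t"], 0.0)
        assert np.allclose(table["p_value"], 1.0)

    def test_constant_offset_zero_variance_flagged(self):
        # dyadic values keep the paired differences exactly constant
        a = [self.profile([0.5 + i / 64]) for i in range(5)]
        b = [self.profile([0.25 + i / 64]) for i in range(5)]
        table = compare_anisotropy(a, b)
        assert table["flag"].iloc[0] == "p<0.001"
        assert "1e-12" in table["note"].iloc[0]

    def test_unequal_sizes_fall_back_to_welch(self):
        a = [self.profile([0.5, 0.6]) for _ in range(4)]
        b = [self.profile([0.3, 0.4]) for _ in range(3)]
        with pytest.warns(UserWarning, match="Welch"):
            table = compare_anisotropy(a, b)
        assert (table["test"] == "welch").all()

    def test_mismatched_scale_grids_error(self):
        a = [self.profile([0.5, 0.6])]
        b = [AnisotropyProfile("q", np.array([1.0, 2.0]),
                               np.array([0.1, 0.2]),
                               np.array([10, 10]))]
        with pytest.raises(ValueError, match="scale grid"):
            compare_anisotropy(a, b)
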