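import itertools

import numpy as np
import pandas as pd
import pytest

from seedtrace import (
    FCMap,
    SeedSpec,
    build_spherical_seed,
    fc_map,
    mask_strength,
    overlap_fraction,
    seed_timeseries,
    seed_to_seed_matrix,
    voxel_permutation_null,
)
from seedtrace.fc import R_CLIP

from conftest import make_image


def brute_force_sphere(img, center, radius):
    out = np.zeros(img.spatial_shape, dtype=bool)
    for idx in np.ndindex(img.spatial_shape):
        xyz = img.affine @ np.array([*idx, 1.0])
        if np.linalg.norm(xyz[:3] - np.asarray(center)) <= radius:
            out[idx] = True
    return out & img.mask_array()


class TestSphericalSeeds:
    def test_tiny_radius_on_voxel_centre_selects_one_voxel(self):
        img = make_image(np.zeros((5, 5, 5)), voxel_mm=(2, 2, 2), tr=None)
        center = tuple(img.voxel_centers_mm()[2, 2, 2])
        seed = build_spherical_seed(SeedSpec("s", center, 0.9), img)
        assert seed.sum() == 1 and seed[2, 2, 2]

    def test_matches_enumeration_on_random_anisotropic_grids(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            shape = tuple(rng.integers(4, 9, size=3))
            voxel = tuple(rng.uniform(0.8, 3.5, size=3))
            img = make_image(np.zeros(shape), voxel_mm=voxel, tr=None)
            centers = img.voxel_centers_mm().reshape(-1, 3)
            center = centers[rng.integers(len(centers))] + rng.uniform(-1, 1, 3)
            radius = float(rng.uniform(1.0, 6.0))
            seed = build_spherical_seed(SeedSpec("s", tuple(center), radius), img)
            np.testing.assert_array_equal(seed, brute_force_sphere(img, center, radius))

    def test_centre_far_outside_brain_errors(self):
        img = make_image(np.zeros((5, 5, 5)), tr=None)
        with pytest.raises(ValueError, match="outside"):
            build_spherical_seed(SeedSpec("s", (100.0, 0.0, 0.0), 3.0), img)

    def test_sphere_outside_mask_errors(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[0, 0, 0] = True
        img = make_image(np.zeros((7, 7, 7)), tr=None, mask=mask)
        center = tuple(img.voxel_centers_mm()[6, 6, 6])
        with pytest.raises(ValueError, match="outside brain"):
            build_spherical_seed(SeedSpec("s", center, 1.5), img)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            SeedSpec("s", (0, 0, 0), 0.0)


class TestSeedTimeseries:
    def test_single_voxel_seed_returns_that_series(self, rng):
        data = rng.standard_normal((3, 3, 3, 10))
        img = make_image(data)
        seed = np.zeros((3, 3, 3), dtype=bool)
        seed[1, 2, 0] = True
        np.testing.assert_array_equal(seed_timeseries(img, seed), data[1, 2, 0])

    def test_opposite_series_cancel(self, rng):
        s = rng.standard_normal(15)
        data = np.zeros((2, 1, 1, 15))
        data[0, 0, 0], data[1, 0, 0] = s, -s
        seed = np.ones((2, 1, 1), dtype=bool)
        np.testing.assert_allclose(seed_timeseries(make_image(data), seed), 0.0, atol=1e-14)

    def test_mean_of_three_voxels(self, rng):
        data = rng.standard_normal((3, 1, 1, 8))
        seed = np.ones((3, 1, 1), dtype=bool)
        np.testing.assert_allclose(
            seed_timeseries(make_image(data), seed), data[:, 0, 0].mean(axis=0)
        )

    def test_empty_seed_errors(self):
        img = make_image(np.zeros((2, 2, 2, 5)))
        with pytest.raises(ValueError, match="empty"):
            seed_timeseries(img, np.zeros((2, 2, 2), dtype=bool))


def image_with_correlations(rs, t=200, seed=0):
    """Voxels constructed to have *exact* sample correlation r with the seed."""
    rng = np.random.default_rng(seed)
    s = rng.standard_normal(t)
    s = (s - s.mean()) / s.std()
    e = rng.standard_normal(t)
    e -= e.mean()
    e -= (e @ s) / (s @ s) * s  # orthogonal to seed
    e /= e.std()
    data = np.zeros((len(rs), 1, 1, t))
    for i, r in enumerate(rs):
        data[i, 0, 0] = r * s + np.sqrt(max(0.0, 1 - r**2)) * e
    return make_image(data), s


class TestFCMap:
    def test_z_equals_arctanh_r(self):
        rs = [-0.999999, -0.5, 0.0, 0.3, 0.5, 0.999999]
        img, s = image_with_correlations(rs)
        fcm = fc_map(img, s)
        z = fcm.z[:, 0, 0]
        np.testing.assert_allclose(z, np.arctanh(rs), atol=1e-12)

    def test_r_half_closed_form(self):
        img, s = image_with_correlations([0.5])
        assert fc_map(img, s).z[0, 0, 0] == pytest.approx(0.5493061443340549, abs=1e-12)

    def test_perfect_correlation_clipped(self):
        img, s = image_with_correlations([1.0, -1.0])
        z = fc_map(img, s).z[:, 0, 0]
        assert z[0] == pytest.approx(np.arctanh(R_CLIP))
        assert z[1] == pytest.approx(-np.arctanh(R_CLIP))

    def test_zero_variance_voxel_invalid(self):
        img, s = image_with_correlations([0.5, 0.2])
        img.data[1, 0, 0] = 7.0  # constant voxel
        fcm = fc_map(img, s)
        assert not fcm.valid[1, 0, 0]
        assert fcm.valid[0, 0, 0]

    def test_constant_seed_errors(self):
        img, _ = image_with_correlations([0.5])
        with pytest.raises(ValueError, match="constant"):
            fc_map(img, np.ones(img.data.shape[3]))

    def test_invariant_to_affine_series_rescaling(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((4, 3, 2, 60))
        img = make_image(data)
        s = rng.standard_normal(60)
        z1 = fc_map(img, s).z
        scaled = make_image(2.5 * data + 7.0)
        z2 = fc_map(scaled, 0.5 * s - 3.0).z
        np.testing.assert_allclose(z1, z2, atol=1e-10)


class TestMaskStrength:
    def _map(self, zvals):
        z = np.asarray(zvals, dtype=float).reshape(-1, 1, 1)
        return FCMap(z, np.ones_like(z, dtype=bool))

    def test_uniform_positive(self):
        fcm = self._map([0.4, 0.4, 0.4])
        assert mask_strength(fcm, np.ones((3, 1, 1), bool)) == pytest.approx(0.4)

    def test_mean_abs_vs_abs_mean_conventions(self):
        fcm = self._map([0.3, -0.3])
        m = np.ones((2, 1, 1), bool)
        assert mask_strength(fcm, m, "mean_abs") == pytest.approx(0.3)
        assert mask_strength(fcm, m, "abs_mean") == pytest.approx(0.0, abs=1e-15)

    def test_matches_direct_loop(self, rng):
        z = rng.standard_normal((5, 4, 3))
        valid = rng.random((5, 4, 3)) > 0.2
        mask = rng.random((5, 4, 3)) > 0.5
        fcm = FCMap(np.where(valid, z, 0.0), valid)
        acc = [abs(z[i]) for i in np.ndindex(z.shape) if valid[i] and mask[i]]
        assert mask_strength(fcm, mask) == pytest.approx(np.mean(acc))

    def test_empty_intersection_errors(self):
        fcm = self._map([0.1])
        with pytest.raises(ValueError, match="no valid"):
            mask_strength(fcm, np.zeros((1, 1, 1), bool))


def toy_map(n_valid, shape, seed=0):
    rng = np.random.default_rng(seed)
    z = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    flat = rng.choice(np.prod(shape), size=n_valid, replace=False)
    valid.reshape(-1)[flat] = True
    z[valid] = rng.standard_normal(n_valid)
    return FCMap(z, valid)


class TestPermutationNull:
    def test_whole_brain_mask_degenerate(self):
        fcm = toy_map(24, (4, 3, 2))
        null, flagged = voxel_permutation_null(fcm, fcm.valid, n_reps=300, rng_seed=0)
        assert null.sd == pytest.approx(0.0, abs=1e-15)
        assert null.mean == pytest.approx(mask_strength(fcm, fcm.valid))
        assert not flagged  # observed == ci_high, strict exceedance

    def test_null_mean_is_brainwide_mean_abs_z(self):
        fcm = toy_map(200, (8, 8, 8), seed=5)
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[fcm.valid] = np.arange(fcm.valid.sum()) < 20
        n_reps = 4000
        null, _ = voxel_permutation_null(fcm, mask, n_reps=n_reps, rng_seed=1)
        pool = np.abs(fcm.z[fcm.valid])
        mc_se = pool.std() / np.sqrt(20) / np.sqrt(n_reps)
        assert abs(null.mean - pool.mean()) < 3 * mc_se

    def test_matches_exhaustive_subset_enumeration(self):
        # 12 valid voxels, mask of 3: all C(12,3) = 220 subsets enumerable
        fcm = toy_map(12, (3, 2, 2), seed=7)
        mask = np.zeros((3, 2, 2), dtype=bool)
        mask[fcm.valid] = np.arange(12) < 3
        pool = np.abs(fcm.z[fcm.valid])
        means = [np.mean(c) for c in itertools.combinations(pool, 3)]
        exact_mean, exact_sd = np.mean(means), np.std(means)
        n_reps = 6000
        null, _ = voxel_permutation_null(fcm, mask, n_reps=n_reps, rng_seed=2)
        assert abs(null.mean - exact_mean) < 3 * exact_sd / np.sqrt(n_reps)
        assert abs(null.sd - exact_sd) < 3 * exact_sd / np.sqrt(2 * n_reps)

    def test_equal_size_masks_have_same_null(self):
        # exchangeability: any two same-size masks share a null distribution
        fcm = toy_map(100, (5, 5, 5), seed=9)
        idx = np.flatnonzero(fcm.valid.reshape(-1))
        m1 = np.zeros(125, bool); m1[idx[:10]] = True
        m2 = np.zeros(125, bool); m2[idx[-10:]] = True
        n1, _ = voxel_permutation_null(fcm, m1.reshape(5, 5, 5), n_reps=4000, rng_seed=3)
        n2, _ = voxel_permutation_null(fcm, m2.reshape(5, 5, 5), n_reps=4000, rng_seed=4)
        assert n1.mean == pytest.approx(n2.mean, abs=4 * n1.sd / np.sqrt(4000) * 2)
        assert n1.sd == pytest.approx(n2.sd, rel=0.1)

    def test_mask_larger_than_brain_errors(self):
        fcm = toy_map(5, (2, 2, 2))
        with pytest.raises(ValueError, match="larger than"):
            voxel_permutation_null(fcm, np.ones((2, 2, 2), bool), n_reps=100)

    def test_reproducible_for_fixed_seed(self):
        fcm = toy_map(30, (4, 4, 2), seed=11)
        mask = np.zeros((4, 4, 2), bool)
        mask[fcm.valid] = np.arange(30) < 5
        a = voxel_permutation_null(fcm, mask, n_reps=500, rng_seed=8, tag="x")
        b = voxel_permutation_null(fcm, mask, n_reps=500, rng_seed=8, tag="x")
        assert a == b


class TestSeedToSeed:
    def _img(self, t=400, seed=0):
        rng = np.random.default_rng(seed)
        return make_image(rng.standard_normal((10, 10, 10, t)) )

    def test_matrix_symmetric_with_nan_diagonal(self):
        img = self._img()
        seeds = [
            SeedSpec("a", tuple(img.voxel_centers_mm()[2, 2, 2]), 2.5),
            SeedSpec("b", tuple(img.voxel_centers_mm()[7, 7, 7]), 2.5),
            SeedSpec("c", tuple(img.voxel_centers_mm()[2, 7, 4]), 2.5),
        ]
        m = seed_to_seed_matrix(img, seeds)
        assert np.isnan(np.diag(m.to_numpy())).all()
        off = m.to_numpy()[~np.eye(3, dtype=bool)]
        np.testing.assert_array_equal(m.to_numpy().T[~np.eye(3, dtype=bool)], off)

    def test_independent_noise_seeds_near_zero(self):
        t = 400
        img = self._img(t=t)
        seeds = [
            SeedSpec("a", tuple(img.voxel_centers_mm()[2, 2, 2]), 2.5),
            SeedSpec("b", tuple(img.voxel_centers_mm()[7, 7, 7]), 2.5),
        ]
        z = seed_to_seed_matrix(img, seeds).loc["a", "b"]
        assert abs(z) < 3 / np.sqrt(t - 3)

    def test_duplicated_seed_at_clip_bound(self):
        img = self._img()
        spec = SeedSpec("a", tuple(img.voxel_centers_mm()[4, 4, 4]), 2.5)
        dup = SeedSpec("a2", spec.center_mm, spec.radius_mm)
        m = seed_to_seed_matrix(img, [spec, dup])
        assert m.loc["a", "a2"] == pytest.approx(np.arctanh(R_CLIP))

    def test_fewer_than_two_seeds_errors(self):
        img = self._img()
        with pytest.raises(ValueError, match="2 seeds"):
            seed_to_seed_matrix(img, [SeedSpec("a", (0, 0, 0), 2.0)])


class TestOverlap:
    def test_fraction_of_mask_inside_seed(self):
        seed = np.zeros((4, 1, 1), bool); seed[:2] = True
        mask = np.zeros((4, 1, 1), bool); mask[1:] = True
        assert overlap_fraction(seed, mask) == pytest.approx(1 / 3)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_fraction(np.ones((2, 1, 1), bool), np.zeros((2, 1, 1), bool))
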