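import math

import numpy as np
import pytest

from sabrrad import manifest as mf
from sabrrad.radiomics import (
    DiscretizationParams,
    ExtractionError,
    discretize,
    extract,
    first_order,
    glcm,
    glcm_features,
    glrlm,
    glrlm_features,
    shape_features,
)

from conftest import make_mask, make_volume

DISC8 = DiscretizationParams(n_levels=8)


def brute_force_glcm(levels, mask, offset, n_levels):
    """O(n^2)-style double-loop pair counter (the independent oracle)."""
    P = np.zeros((n_levels, n_levels))
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                u, v, w = x + offset[0], y + offset[1], z + offset[2]
                if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                    P[levels[x, y, z], levels[u, v, w]] += 1
                    P[levels[u, v, w], levels[x, y, z]] += 1
    return P / P.sum()


def brute_force_glrlm(levels, mask, offset2d, n_levels, max_run):
    """Linear scan per line: walk each start voxel that has no predecessor."""
    R = np.zeros((n_levels, max_run))
    nx, ny, nz = levels.shape
    dx, dy = offset2d
    for z in range(nz):
        for x in range(nx):
            for y in range(ny):
                px, py = x - dx, y - dy
                if 0 <= px < nx and 0 <= py < ny:
                    prev_in = mask[px, py, z] and levels[px, py, z] == levels[x, y, z]
                else:
                    prev_in = False
                if not mask[x, y, z] or prev_in:
                    continue
                run, cx, cy = 0, x, y
                g = levels[x, y, z]
                while 0 <= cx < nx and 0 <= cy < ny and mask[cx, cy, z] and levels[cx, cy, z] == g:
                    run += 1
                    cx, cy = cx + dx, cy + dy
                R[g, run - 1] += 1
    return R


class TestFirstOrder:
    def test_constant_roi_conventions(self):
        vol = make_volume(np.full((3, 3, 1), 100.0))
        f = first_order(vol, make_mask(np.ones((3, 3, 1))))
        assert f["mean"] == 100.0
        assert f["standard_deviation"] == 0.0
        assert f["skewness"] == 0.0
        assert f["kurtosis"] == 0.0
        assert f["energy"] == pytest.approx(100.0**2 * 9)
        assert f["uniformity"] == 1.0
        assert f["entropy"] == 0.0

    def test_symmetric_sample_zero_skewness(self):
        vol = make_volume(np.array([1.0, 2, 3, 4, 5]).reshape(5, 1, 1))
        f = first_order(vol, make_mask(np.ones((5, 1, 1))))
        assert f["mean"] == 3.0
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_skewness_matches_moment_oracle(self):
        v = np.array([1.0, 1, 1, 5])
        vol = make_volume(v.reshape(4, 1, 1))
        f = first_order(vol, make_mask(np.ones((4, 1, 1))))
        m = v.mean()
        m2 = ((v - m) ** 2).mean()
        m3 = ((v - m) ** 3).mean()
        assert f["skewness"] == pytest.approx(m3 / m2**1.5)
        assert f["variance"] == pytest.approx(m2)

    def test_manifest_names_and_count(self, rng):
        vol = make_volume(rng.normal(size=(4, 4, 2)))
        f = first_order(vol, make_mask(np.ones((4, 4, 2))))
        assert tuple(f) == mf.FIRST_ORDER_NAMES
        assert len(f) == 20

    def test_single_voxel_dispersion_zero(self):
        vol = make_volume(np.full((1, 1, 1), -120.0))
        f = first_order(vol, make_mask(np.ones((1, 1, 1))))
        for k in ("variance", "skewness", "interquartile_range", "coefficient_of_variation"):
            assert f[k] == 0.0

    def test_invariant_to_voxel_ordering(self, rng):
        arr = rng.normal(size=(5, 5, 2))
        f1 = first_order(make_volume(arr), make_mask(np.ones((5, 5, 2))))
        f2 = first_order(make_volume(arr.transpose(1, 0, 2)), make_mask(np.ones((5, 5, 2))))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k])

    def test_empty_roi_rejected(self, rng):
        with pytest.raises(ExtractionError, match="empty"):
            first_order(make_volume(rng.normal(size=(3, 3, 3))), make_mask(np.zeros((3, 3, 3))))


class TestGlcm:
    def test_two_equal_voxels_single_diagonal_entry(self):
        vol = make_volume(np.array([[[5.0], [5.0]]]))  # shape (1,2,1)
        P = glcm(vol, make_mask(np.ones((1, 2, 1))), (0, 1, 0), DISC8)
        assert P[0, 0] == 1.0
        assert P.sum() == 1.0

    def test_checkerboard_off_diagonal(self):
        arr = np.indices((6, 6))[0] + np.indices((6, 6))[1]
        arr = (arr % 2).astype(float)[:, :, None]
        P = glcm(make_volume(arr), make_mask(np.ones(arr.shape)), (1, 0, 0), DISC8)
        # all pairs alternate levels: mass off-diagonal, split evenly
        assert P[0, 7] == pytest.approx(0.5)
        assert P[7, 0] == pytest.approx(0.5)

    @pytest.mark.parametrize("offset", list(mf.DIRECTION_OFFSETS.values()))
    def test_matches_brute_force_on_random_patches(self, offset, rng):
        for _ in range(5):
            arr = rng.integers(0, 50, size=(8, 8, 2)).astype(float)
            mask = rng.random((8, 8, 2)) > 0.3
            mask[0, 0, 0] = mask[1, 0, 0] = True
            vol = make_volume(arr)
            disc = DiscretizationParams(n_levels=6)
            P = glcm(vol, make_mask(mask), offset, disc)
            levels = np.where(mask, discretize_masked(arr, mask, disc), -1)
            np.testing.assert_allclose(P, brute_force_glcm(levels, mask, offset, 6), atol=1e-12)

    def test_rotation_invariance_up_to_direction_permutation(self, rng):
        arr = rng.integers(0, 40, size=(7, 7, 1)).astype(float)
        mask = np.ones(arr.shape, dtype=bool)
        disc = DiscretizationParams(n_levels=5)
        rot = np.rot90(arr, axes=(0, 1)).copy()
        rmask = np.rot90(mask, axes=(0, 1)).copy()
        # 90 deg in-plane rotation maps 0 <-> 90 and 45 <-> 135
        for src, dst in (("0", "90"), ("90", "0"), ("45", "135"), ("135", "45")):
            P1 = glcm(make_volume(arr), make_mask(mask), mf.DIRECTION_OFFSETS[src], disc)
            P2 = glcm(make_volume(rot), make_mask(rmask), mf.DIRECTION_OFFSETS[dst], disc)
            f1, f2 = glcm_features(P1), glcm_features(P2)
            for k in f1:
                assert f1[k] == pytest.approx(f2[k], rel=1e-9), (src, dst, k)


def discretize_masked(arr, mask, disc):
    out = np.zeros(arr.shape, dtype=int)
    out[mask] = discretize(arr[mask], disc)
    return out


class TestGlcmFeatures:
    def test_single_entry_matrix(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        f = glcm_features(P)
        assert f["maximum_probability"] == 1.0
        assert f["joint_energy"] == 1.0
        assert f["joint_entropy"] == 0.0

    def test_uniform_matrix_closed_form(self):
        L = 5
        P = np.full((L, L), 1.0 / L**2)
        f = glcm_features(P)
        assert f["maximum_probability"] == pytest.approx(1.0 / L**2)
        assert f["joint_energy"] == pytest.approx(1.0 / L**2)

    def test_joint_energy_matches_direct_sum(self, rng):
        P = rng.random((6, 6))
        P = (P + P.T) / 2
        P /= P.sum()
        f = glcm_features(P)
        direct = sum(P[i, j] ** 2 for i in range(6) for j in range(6))
        assert f["joint_energy"] == pytest.approx(direct)
        assert f["maximum_probability"] == pytest.approx(P.max())

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            glcm_features(np.ones((3, 3)))

    def test_count_and_names(self, rng):
        P = rng.random((4, 4))
        P /= P.sum()
        assert tuple(glcm_features(P)) == mf.GLCM_FEATURE_NAMES


class TestGlrlm:
    def test_constant_row_single_run(self):
        vol = make_volume(np.full((5, 1, 1), 10.0))
        mask = make_mask(np.ones((5, 1, 1)))
        R = glrlm(vol, mask, "0", DISC8)
        assert R.sum() == 1
        assert R[0, 4] == 1  # one run of length 5
        f = glrlm_features(R, 5)
        assert f["run_percentage"] == pytest.approx(1.0 / 5.0)

    def test_alternating_levels_all_runs_length_one(self):
        arr = np.array([0.0, 9, 0, 9, 0, 9]).reshape(6, 1, 1)
        R = glrlm(make_volume(arr), make_mask(np.ones((6, 1, 1))), "0", DISC8)
        f = glrlm_features(R, 6)
        assert f["short_run_emphasis"] == 1.0
        assert f["run_percentage"] == 1.0

    @pytest.mark.parametrize("direction", mf.DIRECTIONS)
    def test_matches_brute_force_scanner(self, direction, rng):
        off = mf.DIRECTION_OFFSETS[direction]
        for _ in range(5):
            arr = rng.integers(0, 30, size=(7, 6, 2)).astype(float)
            mask = rng.random((7, 6, 2)) > 0.25
            mask[0, 0, 0] = True
            disc = DiscretizationParams(n_levels=4)
            R = glrlm(make_volume(arr), make_mask(mask), direction, disc)
            levels = discretize_masked(arr, mask, disc)
            oracle = brute_force_glrlm(levels, mask, (off[0], off[1]), 4, R.shape[1])
            np.testing.assert_array_equal(R, oracle)

    def test_run_broken_at_roi_boundary(self):
        arr = np.full((5, 1, 1), 3.0)
        mask = np.ones((5, 1, 1), dtype=bool)
        mask[2] = False  # hole splits the line into two runs of 2
        R = glrlm(make_volume(arr), make_mask(mask), "0", DISC8)
        assert R[0, 1] == 2
        assert R.sum() == 2


class TestShape:
    def test_single_voxel_volume(self):
        f = shape_features(make_mask(np.ones((1, 1, 1)), spacing=(1, 1, 1)))
        assert f["voxel_volume"] == pytest.approx(1.0)
        assert f["solidity"] == pytest.approx(1.0)

    def test_cube_against_analytic_oracle(self):
        m = np.zeros((14, 14, 14), dtype=bool)
        m[2:12, 2:12, 2:12] = True  # 10x10x10 voxels at 1 mm
        f = shape_features(make_mask(m))
        assert f["voxel_volume"] == pytest.approx(1000.0)
        assert f["mesh_volume"] == pytest.approx(1000.0, rel=0.05)
        assert f["surface_area"] == pytest.approx(600.0, rel=0.10)
        sph = math.pi ** (1 / 3) * (6 * f["mesh_volume"]) ** (2 / 3) / f["surface_area"]
        assert f["sphericity"] == pytest.approx(sph)
        assert f["extent"] == pytest.approx(1.0)
        assert f["maximum_2d_diameter_axial"] == pytest.approx(9 * math.sqrt(2))

    def test_digital_sphere_sphericity_approaches_one(self):
        x, y, z = np.mgrid[0:41, 0:41, 0:41]
        values = []
        for r in (8.0, 16.0):
            m = (x - 20.0) ** 2 + (y - 20.0) ** 2 + (z - 20.0) ** 2 <= r**2
            values.append(shape_features(make_mask(m))["sphericity"])
        assert values[1] > values[0] > 0.9
        assert values[1] > 0.95

    def test_2d_roi_rejected(self):
        m = make_mask(np.ones((4, 4, 1)), is_2d=True)
        with pytest.raises(ExtractionError, match="3D"):
            shape_features(m)

    def test_count_and_names(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[1:5, 1:4, 2:5] = True
        f = shape_features(make_mask(m, spacing=(0.74, 0.74, 5.0)))
        assert tuple(f) == mf.SHAPE_NAMES
        assert all(np.isfinite(v) for v in f.values())


class TestExtract:
    def test_feature_count_contracts(self, one_case):
        from sabrrad.roi import build_all

        rois = build_all(one_case.pd_annotation, one_case.volume, one_case.lung_mask)
        for kind, roi in rois.items():
            feats = extract(one_case.volume, roi, kind)
            expected = mf.N_SOLID_GGO if kind == "solid_ggo" else mf.N_TEXTURE_PER_ROI
            assert len(feats) == expected, kind
            assert all(np.isfinite(v) for v in feats.values())

    def test_avg_direction_is_mean_of_four(self, one_case):
        from sabrrad.roi import build_sphere

        a = one_case.pd_annotation
        roi = build_sphere(a, 20.0, one_case.volume, one_case.lung_mask, kind="sphere20")
        feats = extract(one_case.volume, roi, "sphere20")
        for family, names in (("glcm", mf.GLCM_FEATURE_NAMES), ("glrlm", mf.GLRLM_FEATURE_NAMES)):
            for name in names:
                vals = [feats[f"sphere20|{family}|{name}|{d}"] for d in mf.DIRECTIONS]
                assert feats[f"sphere20|{family}|{name}|avg"] == pytest.approx(np.mean(vals))

    def test_manifest_counts_pinned(self):
        assert mf.N_FIRST_ORDER == 20
        assert mf.N_GLCM == 21
        assert mf.N_GLRLM == 11
        assert mf.N_SHAPE == 24
        assert mf.N_TEXTURE_PER_ROI == 180
        assert mf.N_SOLID_GGO == 384
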