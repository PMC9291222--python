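"""Radiomics oracles: hand-enumerated matrices, brute-force re-implementations,
closed-form shape values and table bookkeeping.

The brute-force functions in this module are deliberately naive (python
loops over voxels and neighbour offsets) and independent of the package's
vectorised implementations.
"""

import numpy as np
import pytest

from aslsubvol.core_io import ImageVolume, Mask
from aslsubvol.radiomics import (
    DiscretizationConfig,
    N_FEATURES_PER_SEQUENCE,
    compute_features,
    compute_matrices,
    discretize,
    extract_table,
    feature_names,
)
from aslsubvol.radiomics.matrices import DIRECTIONS_13, OFFSETS_26
from aslsubvol.radiomics.shape import shape_features

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def brute_glcm(levels):
    """O(voxels x offsets) co-occurrence counting, both orders."""
    shape = levels.shape
    nmax = int(levels.max())
    mat = np.zeros((nmax, nmax))
    for idx in np.ndindex(shape):
        a = levels[idx]
        if a == 0:
            continue
        for off in DIRECTIONS_13:
            for sgn in (1, -1):
                nb = tuple(i + sgn * d for i, d in zip(idx, off))
                if all(0 <= n < s for n, s in zip(nb, shape)):
                    b = levels[nb]
                    if b > 0:
                        mat[a - 1, b - 1] += 1
    return mat


def brute_gldm(levels):
    """Dependence counts: 1 + number of equal-level in-region 26-neighbours."""
    shape = levels.shape
    out = {}
    for idx in np.ndindex(shape):
        a = levels[idx]
        if a == 0:
            continue
        dep = 1
        for off in OFFSETS_26:
            nb = tuple(i + d for i, d in zip(idx, off))
            if all(0 <= n < s for n, s in zip(nb, shape)) and levels[nb] == a:
                dep += 1
        out[(int(a), dep)] = out.get((int(a), dep), 0) + 1
    return out


def brute_ngtdm(levels):
    """Per level: count and summed |level - mean of in-region 26-neighbours|."""
    shape = levels.shape
    n, s = {}, {}
    for idx in np.ndindex(shape):
        a = levels[idx]
        if a == 0:
            continue
        nbs = []
        for off in OFFSETS_26:
            nb = tuple(i + d for i, d in zip(idx, off))
            if all(0 <= m < t for m, t in zip(nb, shape)) and levels[nb] > 0:
                nbs.append(levels[nb])
        if not nbs:
            continue
        n[int(a)] = n.get(int(a), 0) + 1
        s[int(a)] = s.get(int(a), 0.0) + abs(a - np.mean(nbs))
    return n, s


def brute_runs_axis(levels, axis):
    """Run-length encoding along one lattice axis by explicit line walking."""
    runs = {}
    moved = np.moveaxis(levels, axis, -1)
    for line in moved.reshape(-1, moved.shape[-1]):
        i = 0
        while i < len(line):
            if line[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < len(line) and line[j + 1] == line[i]:
                j += 1
            key = (int(line[i]), j - i + 1)
            runs[key] = runs.get(key, 0) + 1
            i = j + 1
    return runs


@pytest.fixture(scope="module")
def random_levels():
    gen = np.random.default_rng(7)
    shape = (6, 5, 4)
    levels = gen.integers(1, 4, size=shape).astype(np.int32)
    levels[gen.random(shape) < 0.25] = 0  # carve an irregular region
    levels[2, 2, 2] = 1  # keep non-empty
    return levels


class TestMatricesAgainstBruteForce:
    def test_glcm(self, random_levels):
        tm = compute_matrices(random_levels, random_levels > 0)
        expected = brute_glcm(random_levels)
        keep = tm.level_values - 1
        np.testing.assert_array_equal(tm.glcm, expected[np.ix_(keep, keep)])

    def test_gldm(self, random_levels):
        tm = compute_matrices(random_levels, random_levels > 0)
        expected = brute_gldm(random_levels)
        for (lev, dep), count in expected.items():
            row = list(tm.level_values).index(lev)
            assert tm.gldm[row, dep - 1] == count
        assert tm.gldm.sum() == sum(expected.values())

    def test_ngtdm(self, random_levels):
        tm = compute_matrices(random_levels, random_levels > 0)
        n, s = brute_ngtdm(random_levels)
        for lev, cnt in n.items():
            row = list(tm.level_values).index(lev)
            assert tm.ngtdm_n[row] == cnt
            assert tm.ngtdm_s[row] == pytest.approx(s[lev], rel=1e-10)

    def test_glrlm_axis_runs_subset(self, random_levels):
        """Axis-aligned runs from explicit line walking appear in the 13-direction total."""
        tm = compute_matrices(random_levels, random_levels > 0)
        total = {}
        for axis in range(3):
            for key, cnt in brute_runs_axis(random_levels, axis).items():
                total[key] = total.get(key, 0) + cnt
        # diagonal directions only ever add runs, never remove axis-aligned ones
        for (lev, ln), cnt in total.items():
            row = list(tm.level_values).index(lev)
            assert tm.glrlm[row, ln - 1] >= cnt

    def test_glszm_zone_count_via_scipy(self, random_levels):
        from scipy import ndimage

        tm = compute_matrices(random_levels, random_levels > 0)
        struct = np.ones((3, 3, 3), bool)
        for row, lev in enumerate(tm.level_values):
            _, n_zones = ndimage.label(random_levels == lev, structure=struct)
            assert tm.glszm[row].sum() == n_zones


class TestHandEnumeratedExamples:
    def test_glcm_checkerboard(self):
        """2x2x1 checkerboard: every in-plane distance-1 pair joins levels 1 and 2."""
        levels = np.array([[[1], [2]], [[2], [1]]], dtype=np.int32)
        tm = compute_matrices(levels, levels > 0)
        # unordered pairs: 4 axis-aligned (all 1-2), diagonal 1-1, anti-diagonal 2-2;
        # each contributes once to P[i,j] and once to P[j,i]
        np.testing.assert_array_equal(tm.glcm, [[2, 4], [4, 2]])

    def test_glrlm_line_region(self):
        """1x4x1 region with levels 1,1,2,2: one run of each level along the axis."""
        levels = np.array([[[1], [1], [2], [2]]], dtype=np.int32)
        tm = compute_matrices(levels, levels > 0)
        # long axis: runs (1, len 2) and (2, len 2); the other 12 directions
        # decompose into single-voxel runs: 2 of each level per direction.
        assert tm.glrlm[0, 1] == 1 and tm.glrlm[1, 1] == 1
        assert tm.glrlm[0, 0] == 24 and tm.glrlm[1, 0] == 24

    def test_glszm_constant_region(self):
        levels = np.ones((3, 4, 2), dtype=np.int32)
        tm = compute_matrices(levels, levels > 0)
        assert tm.glszm.shape == (1, 1)
        assert tm.glszm_sizes[0] == 24
        assert tm.glszm[0, 0] == 1

    def test_single_voxel_region_defined(self):
        levels = np.zeros((3, 3, 3), dtype=np.int32)
        levels[1, 1, 1] = 1
        tm = compute_matrices(levels, levels > 0)
        assert tm.glcm.sum() == 0
        assert tm.gldm[0, 0] == 1  # dependence 1 (the voxel itself)
        assert tm.glrlm[0, 0] == 13  # one unit run per direction
        vol = ImageVolume(np.ones((3, 3, 3)))
        feats = compute_features(vol, Mask.like(vol, levels > 0))
        assert np.isfinite(list(feats.values())).all()


class TestDiscretize:
    def test_bin_width_levels(self):
        vol = ImageVolume(np.arange(100, dtype=float).reshape(4, 5, 5))
        region = Mask.like(vol, np.ones(vol.shape, bool))
        levels, n = discretize(vol, region, DiscretizationConfig("fixed_bin_width", bin_width=25))
        assert n == 4
        assert levels.min() == 1 and levels.max() == 4

    def test_constant_region_single_level(self):
        vol = ImageVolume(np.full((4, 4, 4), 7.0))
        region = Mask.like(vol, np.ones(vol.shape, bool))
        levels, n = discretize(vol, region)
        assert n == 1 and set(np.unique(levels)) == {1}

    def test_bin_count_affine_invariance(self, textured_volume_region):
        vol, region = textured_volume_region
        cfg = DiscretizationConfig("fixed_bin_count", bin_count=16)
        a, _ = discretize(vol, region, cfg)
        b, _ = discretize(vol.with_data(3.0 * vol.data + 40.0), region, cfg)
        np.testing.assert_array_equal(a, b)


class TestFirstOrder:
    def test_constant_region_degeneracies(self):
        vol = ImageVolume(np.full((5, 5, 5), 3.0))
        region = Mask.like(vol, np.ones(vol.shape, bool))
        f = compute_features(vol, region)
        assert f["firstorder_Entropy"] == 0.0
        assert f["firstorder_Uniformity"] == 1.0
        assert f["firstorder_Variance"] == 0.0

    def test_percentile_linear_interpolation(self):
        """Values 1..100: the 10th percentile interpolates to 10.9."""
        data = np.arange(1, 101, dtype=float).reshape(4, 5, 5)
        vol = ImageVolume(data)
        region = Mask.like(vol, np.ones(vol.shape, bool))
        f = compute_features(vol, region)
        assert f["firstorder_10Percentile"] == pytest.approx(10.9)

        def brute_percentile(values, q):  # textbook linear-interpolation percentile
            values = sorted(values)
            pos = (len(values) - 1) * q / 100.0
            lo = int(np.floor(pos))
            hi = min(lo + 1, len(values) - 1)
            return values[lo] + (pos - lo) * (values[hi] - values[lo])

        assert f["firstorder_10Percentile"] == pytest.approx(brute_percentile(data.ravel(), 10))
        assert f["firstorder_90Percentile"] == pytest.approx(brute_percentile(data.ravel(), 90))

    def test_moments_against_direct_formulas(self, textured_volume_region):
        vol, region = textured_volume_region
        f = compute_features(vol, region)
        x = vol.data[region.data]
        assert f["firstorder_Mean"] == pytest.approx(x.mean())
        assert f["firstorder_Variance"] == pytest.approx(((x - x.mean()) ** 2).mean())
        assert f["firstorder_Energy"] == pytest.approx((x**2).sum())
        assert f["firstorder_TotalEnergy"] == pytest.approx((x**2).sum() * 2.0)  # 1x1x2 mm voxels
        assert f["firstorder_RootMeanSquared"] == pytest.approx(np.sqrt((x**2).mean()))
        m2 = ((x - x.mean()) ** 2).mean()
        assert f["firstorder_Skewness"] == pytest.approx(((x - x.mean()) ** 3).mean() / m2**1.5)
        assert f["firstorder_Kurtosis"] == pytest.approx(((x - x.mean()) ** 4).mean() / m2**2)

    def test_outside_voxels_never_leak(self, textured_volume_region):
        vol, region = textured_volume_region
        f1 = compute_features(vol, region)
        poisoned = vol.with_data(np.where(region.data, vol.data, 1e6))
        f2 = compute_features(poisoned, region)
        for name in f1:
            assert f1[name] == pytest.approx(f2[name], rel=1e-12), name


class TestTextureFeatureFormulas:
    def test_glcm_features_from_counts(self, random_levels):
        from aslsubvol.radiomics.features import glcm_features

        tm = compute_matrices(random_levels, random_levels > 0)
        f = glcm_features(tm)
        p = tm.glcm / tm.glcm.sum()
        iv = tm.level_values.astype(float)
        # independent direct sums
        contrast = sum(
            p[i, j] * (iv[i] - iv[j]) ** 2
            for i in range(len(iv)) for j in range(len(iv))
        )
        assert f["Contrast"] == pytest.approx(contrast, rel=1e-10)
        assert f["JointEnergy"] == pytest.approx((p**2).sum(), rel=1e-10)
        assert f["MaximumProbability"] == pytest.approx(p.max(), rel=1e-10)
        assert f["SumAverage"] == pytest.approx(2 * f["JointAverage"], rel=1e-8)
        ent = -sum(p[i, j] * np.log2(p[i, j]) for i in range(len(iv))
                   for j in range(len(iv)) if p[i, j] > 0)
        assert f["JointEntropy"] == pytest.approx(ent, rel=1e-10)
        assert 0.0 <= f["Imc2"] <= 1.0 and 0.0 <= f["MCC"] <= 1.0 + 1e-9

    def test_glrlm_emphasis_formulas(self, random_levels):
        from aslsubvol.radiomics.features import glrlm_features

        tm = compute_matrices(random_levels, random_levels > 0)
        f = glrlm_features(tm)
        c = tm.glrlm.astype(float)
        nr = c.sum()
        lens = np.arange(1, c.shape[1] + 1, dtype=float)
        sre = (c / lens[None, :] ** 2).sum() / nr
        lre = (c * lens[None, :] ** 2).sum() / nr
        assert f["ShortRunEmphasis"] == pytest.approx(sre, rel=1e-10)
        assert f["LongRunEmphasis"] == pytest.approx(lre, rel=1e-10)
        assert f["RunPercentage"] == pytest.approx(nr / tm.n_voxels, rel=1e-10)
        hgl = (c * (tm.level_values[:, None] ** 2)).sum() / nr
        assert f["HighGrayLevelRunEmphasis"] == pytest.approx(hgl, rel=1e-10)

    def test_ngtdm_two_level_closed_form(self):
        """1-D strip 1,1,2: coarseness denominator by direct arithmetic."""
        levels = np.array([[[1], [1], [2]]], dtype=np.int32)
        from aslsubvol.radiomics.features import ngtdm_features

        tm = compute_matrices(levels, levels > 0)
        # voxel A(1): nb mean (1+?) -> neighbours: B(1), so |1 - 1| ... enumerate:
        # A at y=0: nbs {B}; mean 1; diff 0. B at y=1: nbs {A, C} mean 1.5 diff 0.5.
        # C at y=2: nbs {B} mean 1 diff 1.
        np.testing.assert_array_equal(tm.ngtdm_n, [2, 1])
        np.testing.assert_allclose(tm.ngtdm_s, [0.5, 1.0])
        f = ngtdm_features(tm)
        p1, p2 = 2 / 3, 1 / 3
        assert f["Coarseness"] == pytest.approx(1.0 / (p1 * 0.5 + p2 * 1.0), rel=1e-10)


class TestShape:
    def test_cube_closed_form(self):
        """A 10 mm cube: voxel volume 1000 mm3, surface 600 mm2, sphericity 0.806."""
        mask = np.zeros((14, 14, 14), bool)
        mask[2:12, 2:12, 2:12] = True
        f = shape_features(Mask(mask, spacing=(1.0, 1.0, 1.0)))
        assert f["VoxelVolume"] == pytest.approx(1000.0)
        assert f["MeshVolume"] == pytest.approx(1000.0, rel=0.05)
        # marching cubes chamfers the corners: area a few percent under 600
        assert f["SurfaceArea"] == pytest.approx(600.0, rel=0.08)
        assert f["Sphericity"] == pytest.approx((36 * np.pi * 1000.0**2) ** (1 / 3) / 600.0, rel=0.08)
        # principal axes of a cube are equal
        assert f["Elongation"] == pytest.approx(1.0, rel=1e-6)
        assert f["Flatness"] == pytest.approx(1.0, rel=1e-6)
        assert f["Maximum3DDiameter"] == pytest.approx(9 * np.sqrt(3.0), rel=1e-6)
        assert f["Maximum2DDiameterSlice"] == pytest.approx(9 * np.sqrt(2.0), rel=1e-6)

    def test_sphere_sphericity_near_one(self):
        x, y, z = np.indices((30, 30, 30))
        mask = ((x - 14.5) ** 2 + (y - 14.5) ** 2 + (z - 14.5) ** 2) < 12**2
        f = shape_features(Mask(mask))
        assert f["Sphericity"] == pytest.approx(1.0, abs=0.08)
        assert f["SurfaceVolumeRatio"] == pytest.approx(f["SurfaceArea"] / f["MeshVolume"])

    def test_anisotropic_spacing_enters_physically(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        iso = shape_features(Mask(mask, spacing=(1.0, 1.0, 1.0)))
        thick = shape_features(Mask(mask, spacing=(1.0, 1.0, 3.0)))
        assert thick["VoxelVolume"] == pytest.approx(3 * iso["VoxelVolume"])
        assert thick["MajorAxisLength"] > iso["MajorAxisLength"]

    def test_single_voxel_conventions(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        f = shape_features(Mask(mask))
        assert f["VoxelVolume"] == pytest.approx(1.0)
        assert f["Maximum3DDiameter"] == 0.0
        assert f["Elongation"] == 1.0


class TestTableBookkeeping:
    @staticmethod
    def _mini_cohort(n_subjects=2):
        gen = np.random.default_rng(11)
        shape = (16, 16, 12)
        volumes, regions = {}, {}
        for s in range(n_subjects):
            sid = f"sub-{s:02d}"
            vols = {}
            for seq in ("T1WI", "T2_Propeller", "T2_Flair", "CE_T1WI", "ASL"):
                units = "ml_per_100g_per_min" if seq == "ASL" else "arbitrary"
                vols[seq] = ImageVolume(gen.normal(100, 20, shape), intensity_units=units)
            volumes[sid] = vols
            high = np.zeros(shape, bool)
            high[3:8, 3:8, 3:8] = True
            low = np.zeros(shape, bool)
            low[9:14, 4:12, 2:10] = True
            regions[sid] = {"GTV-ASL": Mask(high), "GTV-SUB": Mask(low)}
        return volumes, regions

    def test_535_columns_five_sequences(self):
        volumes, regions = self._mini_cohort()
        table = extract_table(volumes, regions)
        assert table.shape == (4, 535)
        assert len(feature_names()) == N_FEATURES_PER_SEQUENCE == 107
        assert not table.isna().any().any()

    def test_single_sequence_107(self):
        volumes, regions = self._mini_cohort(1)
        single = {sid: {"T1WI": v["T1WI"]} for sid, v in volumes.items()}
        table = extract_table(single, regions)
        assert table.shape == (2, 107)

    def test_rerun_identical_and_hash_stable(self):
        volumes, regions = self._mini_cohort(1)
        a = extract_table(volumes, regions)
        b = extract_table(volumes, regions)
        assert a.equals(b)
        assert a.attrs["config_hash"] == b.attrs["config_hash"]

    def test_shape_replicated_or_deduped(self):
        volumes, regions = self._mini_cohort(1)
        full = extract_table(volumes, regions)
        shape_cols = [c for c in full.columns if "|shape_" in c]
        assert len(shape_cols) == 14 * 5
        # identical across sequences (mask-only features)
        v = full[[f"{seq}|shape_MeshVolume" for seq in ("T1WI", "ASL")]]
        assert (v.iloc[:, 0] == v.iloc[:, 1]).all()
        deduped = extract_table(volumes, regions, dedupe_shape=True)
        assert deduped.shape[1] == 535 - 4 * 14

    def test_geometry_mismatch_names_subject(self):
        volumes, regions = self._mini_cohort(1)
        sid = next(iter(volumes))
        bad = ImageVolume(np.zeros((10, 10, 10)))
        volumes[sid]["T1WI"] = bad
        with pytest.raises(Exception, match=sid):
            extract_table(volumes, regions)
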