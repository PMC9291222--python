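"""GTV delineation, threshold splitting, ROI placement and CBF statistics."""

import numpy as np
import pytest

from aslsubvol.asl_quant import compute_cbf
from aslsubvol.core_io import ImageVolume, Mask
from aslsubvol.phantom import simulate_asl
from aslsubvol.subvolume import (
    EmptyGTVError,
    TargetSet,
    ThresholdRule,
    delineate_gtv,
    perfusion_stats,
    place_rois,
    segment_gtv_asl,
)


def _mask(shape, where=None):
    data = np.zeros(shape, dtype=bool)
    if where is not None:
        data[where] = True
    return Mask(data)


class TestDelineateGTV:
    def test_phantom_recovery_dice(self, small_subject):
        gtv = delineate_gtv(small_subject.structurals["T2_Flair"], small_subject.brain_mask)
        truth = small_subject.gtv_truth
        inter = (gtv.data & truth.data).sum()
        dice = 2 * inter / (gtv.n_voxels + truth.n_voxels)
        assert dice >= 0.95

    def test_uniform_flair_raises(self):
        shape = (16, 16, 16)
        vol = ImageVolume(np.full(shape, 100.0))
        brain = _mask(shape, (slice(2, 14),) * 3)
        with pytest.raises(EmptyGTVError):
            delineate_gtv(vol, brain)

    def test_largest_component_rule(self):
        shape = (30, 20, 10)
        data = np.full(shape, 100.0) + np.random.default_rng(0).normal(0, 1, shape)
        data[2:12, 2:12, 2:8] = 200.0     # big lesion
        data[20:22, 15:17, 2:4] = 200.0   # 10x smaller lesion
        brain = Mask(np.ones(shape, bool))
        gtv = delineate_gtv(ImageVolume(data), brain)
        assert gtv.data[5, 5, 5]
        assert not gtv.data[20, 15, 2]


class TestSegmentGtvAsl:
    @staticmethod
    def _cbf_vol(data):
        from aslsubvol.core_io import UNITS_CBF

        return ImageVolume(np.asarray(data, dtype=float), intensity_units=UNITS_CBF)

    def test_below_threshold_empty(self):
        shape = (12, 12, 12)
        cbf = self._cbf_vol(np.full(shape, 30.0))
        gtv = _mask(shape, (slice(2, 10),) * 3)
        with pytest.warns(RuntimeWarning, match="empty"):
            targets = segment_gtv_asl(cbf, gtv, rule=ThresholdRule("absolute", 44.16))
        assert targets.gtv_asl.is_empty()
        assert targets.gtv_sub.n_voxels == gtv.n_voxels

    def test_noiseless_phantom_core_recovery(self, small_subject):
        """Core at 67, edema at 35, threshold 44.16: volume within 5% of truth."""
        asl = simulate_asl(small_subject.cbf_truth, small_subject.labels, noise_sd=0.0)
        cbf = compute_cbf(asl)
        targets = segment_gtv_asl(cbf, small_subject.gtv_truth,
                                  rule=ThresholdRule("absolute", 44.16))
        assert targets.gtv_asl.n_voxels == pytest.approx(small_subject.core_truth.n_voxels, rel=0.05)

    def test_relative_rule_equals_absolute_at_product(self, small_subject):
        asl = simulate_asl(small_subject.cbf_truth, small_subject.labels, noise_sd=0.0)
        cbf = compute_cbf(asl)
        gtv = small_subject.gtv_truth
        rel = segment_gtv_asl(cbf, gtv, rule=ThresholdRule("relative", 1.49, gm_reference=33.92))
        absolute = segment_gtv_asl(cbf, gtv, rule=ThresholdRule("absolute", 1.49 * 33.92))
        np.testing.assert_array_equal(rel.gtv_asl.data, absolute.gtv_asl.data)

    def test_threshold_monotonicity(self, small_subject):
        """Raising the threshold never grows the GTV-ASL."""
        cbf = compute_cbf(small_subject.asl)
        gtv = small_subject.gtv_truth
        prev = None
        import warnings

        for thr in (20.0, 35.0, 44.16, 55.0, 70.0, 90.0):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cur = segment_gtv_asl(cbf, gtv, rule=ThresholdRule("absolute", thr)).gtv_asl
            if prev is not None:
                assert (cur.data <= prev.data).all()
            prev = cur

    def test_target_set_algebra_enforced(self, small_subject):
        cbf = compute_cbf(small_subject.asl)
        targets = segment_gtv_asl(cbf, small_subject.gtv_truth, exclusion=small_subject.exclusion)
        gtv, asl, sub = targets.gtv.data, targets.gtv_asl.data, targets.gtv_sub.data
        assert (asl <= gtv).all()
        assert not (asl & sub).any()
        assert (sub == (gtv & ~asl)).all()
        assert targets.gtv_asl.n_voxels + targets.gtv_sub.n_voxels == targets.gtv.n_voxels
        # and the constructor rejects broken algebra
        with pytest.raises(ValueError, match="subset"):
            TargetSet(gtv=targets.gtv_sub, gtv_asl=targets.gtv_asl,
                      gtv_sub=targets.gtv_sub, exclusion=targets.exclusion)

    def test_exclusion_respected(self):
        shape = (14, 14, 14)
        data = np.full(shape, 20.0)
        data[4:10, 4:10, 4:10] = 80.0
        cbf = self._cbf_vol(data)
        gtv = _mask(shape, (slice(2, 12),) * 3)
        excl = _mask(shape, (slice(4, 7), slice(4, 7), slice(4, 7)))
        targets = segment_gtv_asl(cbf, gtv, exclusion=excl)
        assert not (targets.gtv_asl.data & excl.data).any()
        assert targets.gtv_asl.data[8, 8, 8]

    def test_otsu_rule_is_level_invariant(self, small_subject):
        """The adaptive rule finds the core whether perfusion is globally high or low."""
        base = small_subject.cbf_truth
        for gain in (0.7, 1.4):
            scaled = base.with_data(base.data * gain)
            asl = simulate_asl(scaled, small_subject.labels, noise_sd=0.0)
            targets = segment_gtv_asl(compute_cbf(asl), small_subject.gtv_truth,
                                      rule=ThresholdRule(kind="otsu"))
            assert targets.gtv_asl.n_voxels == pytest.approx(
                small_subject.core_truth.n_voxels, rel=0.1
            )

    def test_bad_rules_rejected(self):
        with pytest.raises(ValueError):
            ThresholdRule("absolute", -5.0)
        with pytest.raises(ValueError):
            ThresholdRule("relative", 1.49)  # missing gm_reference
        with pytest.raises(ValueError):
            ThresholdRule("nonsense", 1.0)
        assert ThresholdRule.parse("absolute:44.16").value == 44.16
        assert ThresholdRule.parse("otsu").kind == "otsu"


class TestPerfusionStats:
    def test_constant_region(self):
        shape = (8, 8, 8)
        data = np.full(shape, 25.0)
        data[:4] = 50.0
        vol = ImageVolume(data)
        region = _mask(shape, (slice(0, 4),))
        reference = _mask(shape, (slice(4, 8),))
        stats = perfusion_stats(vol, region, reference)
        assert (stats.cbf_max, stats.cbf_min, stats.cbf_mean) == (50.0, 50.0, 50.0)
        assert stats.r_cbf_mean == pytest.approx(2.0)

    def test_three_value_region(self):
        shape = (4, 4, 4)
        data = np.zeros(shape)
        data[0, 0, :3] = [30.0, 60.0, 90.0]
        data[3, 3, 3] = 10.0
        vol = ImageVolume(data)
        region = _mask(shape)
        region.data[0, 0, :3] = True
        reference = _mask(shape, (3, 3, 3))
        stats = perfusion_stats(vol, region, reference)
        assert (stats.cbf_max, stats.cbf_min, stats.cbf_mean) == (90.0, 30.0, 60.0)

    def test_empty_region_rejected(self):
        vol = ImageVolume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            perfusion_stats(vol, _mask((4, 4, 4)), _mask((4, 4, 4), (0, 0, 0)))


class TestPlaceRois:
    def test_roi_geometry_on_phantom(self, canonical_subject):
        subj = canonical_subject
        cbf = compute_cbf(subj.asl)
        targets = segment_gtv_asl(cbf, subj.gtv_truth, rule=ThresholdRule("absolute", 44.16))
        rois = place_rois(cbf, targets, subj.gm_mask, laterality="unilateral", area_mm2=120.0)
        assert (rois.roi_t.data <= targets.gtv_asl.data).all()
        for roi in rois.roi_e:
            assert (roi.data <= targets.gtv_sub.data).all()
            assert 100.0 <= roi.n_voxels * 9.0  # 3x3 mm in-plane pixels
        assert not (rois.roi_n.data & targets.gtv.data).any()
        assert (rois.roi_n.data <= subj.gm_mask.data).all()
        assert 100.0 <= rois.areas_mm2["roi_n"] <= 160.0

    def test_mirror_reference_for_unilateral(self, canonical_subject):
        from scipy import ndimage

        subj = canonical_subject
        cbf = compute_cbf(subj.asl)
        targets = segment_gtv_asl(cbf, subj.gtv_truth, rule=ThresholdRule("absolute", 44.16))
        rois = place_rois(cbf, targets, subj.gm_mask, laterality="unilateral")
        lesion_x = ndimage.center_of_mass(targets.gtv.data)[0]
        roi_x = ndimage.center_of_mass(rois.roi_n.data)[0]
        mid = (subj.labels.shape[0] - 1) / 2
        # ROI-N sits on the opposite side of the mid-sagittal plane
        assert (lesion_x - mid) * (roi_x - mid) < 0

    def test_disc_area_on_1mm_grid(self):
        """120 mm2 disc rasterised on a 1 mm grid has 120 +/- 4 voxels."""
        from aslsubvol.subvolume import _disc

        disc = _disc((40, 40, 5), (1.0, 1.0, 1.0), (20.0, 20.0), 2, 120.0)
        assert abs(int(disc.sum()) - 120) <= 4

    def test_single_voxel_gtv_asl_clips_with_warning(self):
        from aslsubvol.core_io import UNITS_CBF

        shape = (20, 20, 8)
        data = np.full(shape, 20.0)
        data[10, 10, 4] = 90.0
        cbf = ImageVolume(data, intensity_units=UNITS_CBF)
        gtv = _mask(shape, (slice(8, 13), slice(8, 13), slice(3, 6)))
        asl_mask = _mask(shape, (10, 10, 4))
        targets = TargetSet(gtv=gtv, gtv_asl=asl_mask,
                            gtv_sub=gtv - asl_mask, exclusion=_mask(shape))
        gm = _mask(shape, (slice(0, 4), slice(0, 20), slice(0, 8)))
        with pytest.warns(RuntimeWarning):
            rois = place_rois(cbf, targets, gm)
        assert rois.roi_t.n_voxels == 1
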