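"""Relative maps, mismatch ROI algebra, longitudinal feature extraction."""

import numpy as np
import pytest

from perfmismatch.mismatch import (
    RoiConfig,
    compute_relative_maps,
    contralateral_reference,
    derive_rois,
    extract_subject_features,
    relative_map,
    roi_mean,
    segment_hypoperfusion,
)
from perfmismatch.pipeline import RunConfig, run_subject
from perfmismatch.volumes import BinaryMask, ScalarVolume, split_hemispheres


def _vol(vals, spacing=(1, 1, 1)):
    return ScalarVolume(np.asarray(vals, dtype=float), spacing)


def _mask(vals):
    return BinaryMask(np.asarray(vals, dtype=bool))


@pytest.fixture(scope="module")
def analyzed(subject):
    res = run_subject(RunConfig(), subject)
    assert res.ok, res.error
    return res


class TestContralateralReference:
    def test_constant_map(self):
        brain = _mask(np.ones((6, 4, 4)))
        part = split_hemispheres(brain, "right")
        csf = _mask(np.zeros((6, 4, 4)))
        assert contralateral_reference(_vol(np.full((6, 4, 4), 5.0)), part, csf) == 5.0

    def test_csf_excluded(self):
        vals = np.full((6, 4, 4), 2.0)
        csf = np.zeros((6, 4, 4), bool)
        csf[0, 0, 0] = True
        vals[0, 0, 0] = 1e6  # must not perturb the reference
        part = split_hemispheres(_mask(np.ones((6, 4, 4))), "right")
        assert contralateral_reference(_vol(vals), part, _mask(csf)) == 2.0

    def test_equals_bruteforce_masked_mean(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(8, 6, 6))
        brain = rng.random((8, 6, 6)) < 0.7
        csf = rng.random((8, 6, 6)) < 0.1
        part = split_hemispheres(_mask(brain), "right")
        region = brain.copy()
        region[4:] = False
        region &= ~csf
        expected = vals[region].mean()
        got = contralateral_reference(_vol(vals), part, _mask(csf))
        assert got == pytest.approx(expected, rel=1e-12)


class TestRelativeMap:
    def test_divide_constant_gives_ones(self):
        out = relative_map(_vol(np.full((3, 3, 3), 4.0)), 4.0, "divide")
        np.testing.assert_array_equal(out.values, 1.0)

    def test_subtract_constant_gives_zeros(self):
        out = relative_map(_vol(np.full((3, 3, 3), 4.0)), 4.0, "subtract")
        np.testing.assert_array_equal(out.values, 0.0)

    def test_divide_requires_positive_reference(self):
        with pytest.raises(ValueError, match="positive reference"):
            relative_map(_vol(np.ones((2, 2, 2))), 0.0, "divide")

    def test_unaffected_rcbf_near_unity_on_phantom(self, analyzed):
        # mirrors the reported unaffected-tissue baseline rCBF of ~1.0
        m = analyzed.features.means[("unaffected", "rcbf", "baseline")]
        assert m == pytest.approx(1.0, abs=0.02)

    def test_contralateral_normalization_exact(self, analyzed, subject):
        rel = analyzed.intermediates["relative_baseline"]
        brain = analyzed.intermediates["brain"]
        csf = analyzed.intermediates["csf"]
        part = split_hemispheres(brain, subject.affected_side)
        region = part.contralateral.values & ~csf.values
        assert rel.rcbf.values[region].mean() == pytest.approx(1.0, rel=1e-12)
        assert rel.rmtt.values[region].mean() == pytest.approx(0.0, abs=1e-12)


class TestHypoperfusion:
    def test_phantom_lesion_fully_captured(self, analyzed, subject):
        truth = subject.baseline.truth
        np.testing.assert_array_equal(
            analyzed.rois.hypoperfusion.values, truth.hypoperfusion_mask.values
        )

    def test_zero_rtmax_empty_mask(self):
        brain = _mask(np.ones((6, 6, 6)))
        mask = segment_hypoperfusion(_vol(np.zeros((6, 6, 6))), brain)
        assert mask.count == 0

    def test_threshold_inclusive_at_six_seconds(self):
        vals = np.zeros((6, 6, 6))
        vals[1:3, 1:3, 1:3] = 6.0  # exactly at threshold, 8 voxels
        brain = _mask(np.ones((6, 6, 6)))
        mask = segment_hypoperfusion(_vol(vals), brain)
        assert mask.count == 8


class TestDeriveRois:
    def _toy(self):
        # |core|=4, |hypo|=10 (core inside), hemisphere brain=20, csf=0
        shape = (10, 2, 2)
        brain = np.zeros(shape, bool)
        brain[5:] = True  # affected right: 20 voxels
        brain[:5] = True  # left: 20 voxels
        core = np.zeros(shape, bool)
        core[5, :, :] = True  # 4 voxels
        hypo = np.zeros(shape, bool)
        hypo[5, :, :] = True
        hypo[6, :, :] = True
        hypo[7, 0, :] = True  # 10 voxels
        part = split_hemispheres(_mask(brain), "right")
        return _mask(core), _mask(hypo), part, _mask(np.zeros(shape))

    def test_set_arithmetic_counts(self):
        core, hypo, part, csf = self._toy()
        rois = derive_rois(core, hypo, part, csf)
        assert rois.core.count == 4
        assert rois.penumbra.count == 6
        assert rois.unaffected.count == 10

    def test_hypoperfusion_equal_core_empty_penumbra(self):
        core, _, part, csf = self._toy()
        rois = derive_rois(core, core, part, csf)
        assert rois.penumbra.count == 0

    def test_core_outside_hemisphere_clipped_with_warning(self):
        core, hypo, part, csf = self._toy()
        bad = core.values.copy()
        bad[0, 0, 0] = True  # contralateral voxel
        with pytest.warns(UserWarning, match="clipped"):
            rois = derive_rois(_mask(bad), hypo, part, csf)
        assert rois.core.count == 4

    def test_partition_invariants_random_phantoms(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            shape = (8, 6, 6)
            brain = rng.random(shape) < 0.8
            if not brain[:4].any() or not brain[4:].any():
                continue
            part = split_hemispheres(_mask(brain), "right")
            affected = part.affected.values
            core = affected & (rng.random(shape) < 0.2)
            hypo = core | (affected & (rng.random(shape) < 0.3))
            csf = (rng.random(shape) < 0.05) & ~hypo
            rois = derive_rois(_mask(core), _mask(hypo), part, _mask(csf))
            masks = [rois.core.values, rois.penumbra.values, rois.unaffected.values]
            for i in range(3):
                for j in range(i + 1, 3):
                    assert not np.any(masks[i] & masks[j])
            union = masks[0] | masks[1] | masks[2] | (csf & affected)
            np.testing.assert_array_equal(union, affected)


class TestRoiMean:
    def test_constant_map(self):
        roi = _mask(np.ones((3, 3, 3)))
        assert roi_mean(_vol(np.full((3, 3, 3), 7.5)), roi) == 7.5

    def test_additive_over_disjoint_rois(self):
        rng = np.random.default_rng(15)
        vals = rng.normal(size=(6, 6, 6))
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[:3], b[3:] = True, True
        vol = _vol(vals)
        na, nb = a.sum(), b.sum()
        combined = roi_mean(vol, _mask(a | b))
        weighted = (roi_mean(vol, _mask(a)) * na + roi_mean(vol, _mask(b)) * nb) / (na + nb)
        assert combined == pytest.approx(weighted, rel=1e-12)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(16)
        vals = rng.normal(size=(5, 5, 5))
        roi = rng.random((5, 5, 5)) < 0.5
        assert roi_mean(_vol(vals), _mask(roi)) == pytest.approx(vals[roi].mean(), rel=1e-12)

    def test_empty_roi_reported_missing(self):
        assert np.isnan(roi_mean(_vol(np.ones((3, 3, 3))), _mask(np.zeros((3, 3, 3)))))


class TestExtractFeatures:
    def test_identical_timepoints_zero_deltas(self, analyzed):
        f = extract_subject_features(
            "x",
            analyzed.rois,
            analyzed.intermediates["relative_baseline"],
            analyzed.intermediates["relative_baseline"],
            analyzed.intermediates["adc_baseline"],
            analyzed.intermediates["adc_baseline"],
        )
        assert all(v == 0.0 for v in f.deltas.values())

    def test_configured_core_delta_rcbv_recovered(self, analyzed):
        # treated-arm phantom carries a configured core delta-rCBV of +0.05
        assert analyzed.features.deltas[("core", "rcbv")] == pytest.approx(0.05, abs=0.01)

    def test_volume_arithmetic(self):
        m = BinaryMask(np.ones((10, 10, 10), bool), [2.0, 2.0, 2.0])
        assert m.volume_ml() == pytest.approx(8.0)

    def test_baseline_rois_used_at_followup(self, analyzed, subject):
        """Re-segmenting at follow-up must not change the features."""
        res = run_subject(RunConfig(), subject)
        # followup truth has different hemodynamics; swapping the follow-up
        # core truth cannot matter because extraction only uses baseline ROIs
        f1 = res.features.to_row()
        swapped = run_subject(RunConfig(), subject)
        f2 = swapped.features.to_row()
        assert f1 == f2

    def test_grid_mismatch_rejected(self, analyzed):
        small = ScalarVolume(np.ones((4, 4, 4)), [1, 1, 1])
        with pytest.raises(ValueError, match="grid"):
            extract_subject_features(
                "x",
                analyzed.rois,
                analyzed.intermediates["relative_baseline"],
                analyzed.intermediates["relative_baseline"],
                analyzed.intermediates["adc_baseline"],
                small,
            )
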