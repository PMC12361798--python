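"""Diagnosis rules, region parsing, severe-zone geometry, ROC, segmenter."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from echomvp.data import AL, MVP, PL, DataError, ValidationError
from echomvp.diagnosis import (
    FrameDiagnosis,
    SegTrainConfig,
    SegModel,
    diagnose_frame,
    diagnose_patient,
    judge_severe_zone,
    parse_regions,
    roc_over_proportion,
    train_segmenter,
)
from echomvp.metrics import overlap_metrics


def leaflet_scaffold(h=64, w=64, y_ann=32):
    """A simple two-band mask: AL above the annulus row, PL below.

    Bands stand 3 px off the annulus so a 3-px dilation of one leaflet
    cannot reach a blob attached to the other.
    """
    mask = np.zeros((h, w), dtype=np.int8)
    mask[y_ann - 8 : y_ann - 3, 8:56] = AL
    mask[y_ann + 3 : y_ann + 8, 8:56] = PL
    return mask


class TestFrameRule:
    def test_no_mvp_pixels(self):
        assert not diagnose_frame(leaflet_scaffold()).has_mvp

    def test_single_pixel_counts_with_default_min_area(self):
        mask = leaflet_scaffold()
        mask[40, 30] = MVP
        d = diagnose_frame(mask)
        assert d.has_mvp and d.mvp_area == 1

    def test_min_area_threshold(self):
        mask = leaflet_scaffold()
        mask[40, 30:33] = MVP
        assert not diagnose_frame(mask, min_area=5).has_mvp
        assert diagnose_frame(mask, min_area=3).has_mvp


class TestPatientRule:
    def _diags(self, flags, areas=None):
        areas = areas or [10 * f for f in flags]
        return [
            FrameDiagnosis(frame_index=i, has_mvp=bool(f), mvp_area=a)
            for i, (f, a) in enumerate(zip(flags, areas))
        ]

    def test_three_of_five_is_positive(self):
        p = diagnose_patient(self._diags([1, 1, 1, 0, 0]))
        assert p.proportion == pytest.approx(0.6) and p.is_mvp

    def test_exactly_half_is_negative(self):
        p = diagnose_patient(self._diags([1, 1, 0, 0]))
        assert p.proportion == pytest.approx(0.5) and not p.is_mvp

    def test_index_frame_is_argmax_area_lowest_on_tie(self):
        p = diagnose_patient(self._diags([1, 1, 1], areas=[10, 50, 30]))
        assert p.index_frame == 1
        p = diagnose_patient(self._diags([1, 1], areas=[50, 50]))
        assert p.index_frame == 0

    def test_no_systolic_frames_rejected(self):
        with pytest.raises(DataError):
            diagnose_patient([])

    @given(st.lists(st.booleans(), min_size=1, max_size=20))
    def test_monotone_in_added_mvp_frames(self, flags):
        base = diagnose_patient(self._diags(flags))
        extended = diagnose_patient(
            self._diags(flags + [True], areas=[10 * f for f in flags] + [5])
        )
        if base.is_mvp:
            assert extended.is_mvp


class TestParseRegions:
    def test_empty_mask(self):
        assert parse_regions(np.zeros((16, 16), dtype=np.int8)) == []

    def test_two_disjoint_blobs_found_with_areas(self):
        mask = np.zeros((32, 32), dtype=np.int8)
        mask[2:6, 2:6] = MVP  # 16 px
        mask[20:25, 20:26] = MVP  # 30 px
        regions = parse_regions(mask)
        assert sorted(r.area for r in regions) == [16, 30]
        assert all(r.class_id == MVP for r in regions)

    def test_small_component_filtered(self):
        mask = np.zeros((16, 16), dtype=np.int8)
        mask[2:4, 2:4] = MVP  # 4 px
        assert parse_regions(mask, min_component_area=5) == []

    def test_areas_sum_to_class_pixel_counts(self, rng):
        mask = (rng.random((48, 48)) * 4).astype(np.int8)
        regions = parse_regions(mask, min_component_area=1)
        for k in (AL, PL, MVP):
            total = sum(r.area for r in regions if r.class_id == k)
            assert total == int((mask == k).sum())

    def test_eight_connectivity(self):
        mask = np.zeros((8, 8), dtype=np.int8)
        mask[1, 1] = MVP
        mask[2, 2] = MVP  # diagonal touch: one component
        assert len(parse_regions(mask)) == 1


class TestJudgeSevereZone:
    def test_pl_middle_third(self):
        mask = leaflet_scaffold()
        mask[33:40, 28:36] = MVP  # below the annulus, mid chord, touching PL
        call = judge_severe_zone(parse_regions(mask))
        assert call.ssz_apl == "PL"
        assert call.ssz_ssz == "P2"
        assert call.dsz_apl == (False, True)

    def test_al_left_third(self):
        mask = leaflet_scaffold()
        mask[24:31, 9:15] = MVP  # above the annulus, left end, touching AL
        call = judge_severe_zone(parse_regions(mask))
        assert call.ssz_apl == "AL"
        assert call.ssz_ssz == "A1"

    def test_blobs_on_both_leaflets(self):
        mask = leaflet_scaffold()
        mask[24:30, 10:16] = MVP
        mask[35:41, 40:46] = MVP
        call = judge_severe_zone(parse_regions(mask))
        assert call.dsz_apl == (True, True)

    def test_requires_an_mvp_component(self):
        with pytest.raises(ValidationError):
            judge_severe_zone(parse_regions(leaflet_scaffold()))

    def test_recovers_generator_truth(self, mvp_case):
        t = mvp_case.phase_labels.systolic_indices()[0]
        call = judge_severe_zone(parse_regions(mvp_case.masks[t]))
        assert call.ssz_ssz == mvp_case.severe_zone_truth


class TestRoc:
    def test_perfect_separation(self):
        records = [(0.9, True), (0.8, True), (0.2, False), (0.1, False)]
        assert roc_over_proportion(records).auc == pytest.approx(1.0)

    def test_all_scores_equal(self):
        records = [(0.5, True), (0.5, False), (0.5, True), (0.5, False)]
        assert roc_over_proportion(records).auc == pytest.approx(0.5)

    def test_concordant_pair_fraction(self):
        records = [(0.9, True), (0.6, True), (0.4, False), (0.7, False)]
        assert roc_over_proportion(records).auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_over_proportion([(0.4, True), (0.9, True)])

    @given(seed=st.integers(0, 1000))
    def test_auc_equals_concordance_oracle(self, seed):
        local = np.random.default_rng(seed)
        scores = local.random(12)
        truth = local.random(12) > 0.5
        if truth.all() or not truth.any():
            return
        auc = roc_over_proportion(list(zip(scores, truth))).auc
        pos = scores[truth]
        neg = scores[~truth]
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


class TestSegmenterTraining:
    def test_empty_dataset_rejected(self):
        with pytest.raises(DataError):
            train_segmenter([], [])

    def test_single_class_masks_rejected(self, control_case):
        frames = [control_case.cine.frames[0]]
        masks = [np.zeros_like(control_case.masks[0])]
        with pytest.raises(DataError):
            train_segmenter(frames, masks)

    def test_single_image_memorization(self, mvp_case):
        """One frame, 200 steps: the net must reproduce its own training mask."""
        t = mvp_case.phase_labels.systolic_indices()[0]
        frame, mask = mvp_case.cine.frames[t], mvp_case.masks[t]
        model, _ = train_segmenter(
            [frame], [mask],
            SegTrainConfig(epochs=200, batch_size=1, lr=2e-2, input_size=192,
                           augment_flip=False, seed=0),
        )
        pred = model.segment(frame)
        dices = [
            overlap_metrics(pred == k, mask == k).dice for k in (AL, PL, MVP)
        ]
        assert np.mean(dices) >= 0.95

    def test_segment_codomain_and_shape(self, mvp_case):
        net_model, _ = train_segmenter(
            [mvp_case.cine.frames[0]], [mvp_case.masks[0]],
            SegTrainConfig(epochs=1, batch_size=1, seed=0),
        )
        pred = net_model.segment(mvp_case.cine.frames[1])
        assert pred.shape == mvp_case.cine.frames[1].shape
        assert set(np.unique(pred)) <= {0, 1, 2, 3}

    def test_save_load_roundtrip(self, tmp_path, mvp_case):
        model, _ = train_segmenter(
            [mvp_case.cine.frames[0]], [mvp_case.masks[0]],
            SegTrainConfig(epochs=1, batch_size=1, seed=0),
        )
        model.save(tmp_path / "seg.npz")
        loaded = SegModel.load(tmp_path / "seg.npz")
        np.testing.assert_array_equal(
            model.segment(mvp_case.cine.frames[0]), loaded.segment(mvp_case.cine.frames[0])
        )
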