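"""Active-if ensemble arithmetic, cycle parsing, and classifier training."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from echomvp.data import DataError, SYSTOLE, DIASTOLE, ValidationError
from echomvp.oracle import ConstantPhaseModel
from echomvp.phase import (
    CyclePrediction,
    LogitRecord,
    PhaseModel,
    PhaseTrainConfig,
    active_if_select,
    confidence,
    parse_cycles,
    positive_probability,
    predict_phase,
    train_phase_classifier,
)


class TestPositiveProbability:
    def test_equal_logits_give_half(self):
        assert positive_probability(LogitRecord(0.0, 0.0)) == 0.5

    def test_two_term_softmax_value(self):
        # exp(2)/(exp(1)+exp(2)) evaluated at high precision
        assert positive_probability(1.0, 2.0) == pytest.approx(0.7310585786300049, abs=1e-9)

    def test_extreme_logits_do_not_overflow(self):
        assert positive_probability(0.0, 1000.0) == pytest.approx(1.0, abs=1e-12)
        assert positive_probability(1000.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            positive_probability(np.nan, 0.0)
        with pytest.raises(ValidationError):
            LogitRecord(np.inf, 0.0)


class TestConfidence:
    @pytest.mark.parametrize(
        "p,expected", [(0.5, 0.0), (1.0, 1.0), (0.0, 1.0), (0.7310586, 0.4621172)]
    )
    def test_values(self, p, expected):
        assert confidence(p) == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            confidence(1.2)

    @given(st.floats(-20, 20))
    def test_equal_logit_pairs_have_zero_confidence(self, o):
        assert confidence(positive_probability(o, o)) == pytest.approx(0.0, abs=1e-12)


class TestActiveIf:
    @pytest.mark.parametrize(
        "conf_a,conf_b,c,expected",
        [
            (0.5, 0.9, 0.4, "A"),  # A not below C: activation fails
            (0.3, 0.6, 0.4, "B"),  # both conditions pass
            (0.3, 0.3, 0.4, "A"),  # strict inequality fails on tie
            (0.0, 0.0, 0.0, "A"),
            (0.39, 0.4, 0.4, "B"),
        ],
    )
    def test_rule(self, conf_a, conf_b, c, expected):
        assert active_if_select(conf_a, conf_b, c) == expected

    def test_matches_truth_table_oracle_on_grid(self):
        grid = np.linspace(0, 1, 51)
        for c in (0.0, 0.4, 1.0):
            for ca in grid:
                for cb in grid:
                    expected = "B" if (ca < c and cb > ca) else "A"
                    assert active_if_select(ca, cb, c) == expected


class TestPredictPhase:
    def test_confident_main_network_wins(self):
        label, dec = predict_phase(None, ConstantPhaseModel(0, 10), ConstantPhaseModel(10, 0))
        assert label == SYSTOLE and dec.chosen == "A"

    def test_unsure_main_yields_to_secondary(self):
        # A: p_pos ~ 0.525 (conf ~ 0.05); B: certain systole
        label, dec = predict_phase(None, ConstantPhaseModel(0.1, 0.0), ConstantPhaseModel(0, 10))
        assert dec.chosen == "B" and label == SYSTOLE

    def test_confident_main_ignores_confident_secondary(self):
        label, dec = predict_phase(None, ConstantPhaseModel(10, 0), ConstantPhaseModel(0, 10))
        assert label == DIASTOLE and dec.chosen == "A"


class TestParseCycles:
    def test_linear_scan_example(self):
        labels = ["diastole", "diastole", "systole", "systole", "systole",
                  "diastole", "diastole", "systole", "systole", "diastole"]
        cp = parse_cycles(np.array(labels))
        assert cp.systole_periods == [(2, 4), (7, 8)]
        assert cp.ed_frames == [2, 7]
        assert cp.es_frames == [4, 8]

    def test_all_diastole(self):
        assert parse_cycles([0, 0, 0]).n_cycles == 0

    def test_single_systolic_frame(self):
        cp = parse_cycles([1])
        assert cp.systole_periods == [(0, 0)]
        assert cp.ed_frames == [0] and cp.es_frames == [0]

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            parse_cycles([])

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    def test_idempotent_after_reconstruction(self, labels):
        cp = parse_cycles(labels)
        rebuilt = np.zeros(len(labels), dtype=int)
        for s, e in cp.systole_periods:
            rebuilt[s : e + 1] = 1
        assert np.array_equal(rebuilt, np.asarray(labels))
        cp2 = parse_cycles(rebuilt)
        assert cp2.systole_periods == cp.systole_periods

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    def test_label_swap_symmetry(self, labels):
        """Complementary runs: systole periods of 1-x are the diastole runs of x."""
        arr = np.asarray(labels)
        runs_pos = parse_cycles(arr).systole_periods
        runs_neg = parse_cycles(1 - arr).systole_periods
        covered = set()
        for s, e in runs_pos + runs_neg:
            covered |= set(range(s, e + 1))
        assert covered == set(range(len(labels)))
        # ED of a complementary run is the frame after an ES of the original
        for s, _ in runs_neg:
            if s > 0:
                assert arr[s - 1] == 1 and s - 1 in [e for _, e in runs_pos]

    def test_invariant_one_ed_es_pair_per_period(self):
        with pytest.raises(ValidationError):
            CyclePrediction([(0, 1)], [0], [])


class TestTraining:
    def test_empty_dataset_rejected(self):
        with pytest.raises(DataError):
            train_phase_classifier([], "main")

    def test_single_class_dataset_rejected(self, control_case):
        import copy

        only_diastole = copy.deepcopy(control_case)
        only_diastole.phase_labels.labels[:] = 0
        with pytest.raises(DataError):
            train_phase_classifier([only_diastole], "main")

    def test_unknown_arch_rejected(self, control_case):
        with pytest.raises(ValidationError):
            train_phase_classifier([control_case], "resnet")

    def test_same_seed_same_first_epoch_loss(self, control_case, mvp_case):
        cfg = PhaseTrainConfig(epochs=1, seed=4)
        _, la = train_phase_classifier([control_case, mvp_case], "secondary", cfg)
        _, lb = train_phase_classifier([control_case, mvp_case], "secondary", cfg)
        assert la[0] == pytest.approx(lb[0], rel=1e-9)

    def test_save_load_roundtrip_preserves_logits(self, tmp_path, control_case, mvp_case):
        cfg = PhaseTrainConfig(epochs=1, seed=4)
        model, _ = train_phase_classifier([control_case, mvp_case], "main", cfg)
        model.save(tmp_path / "m.npz")
        loaded = PhaseModel.load(tmp_path / "m.npz")
        frame = control_case.cine.frames[0]
        np.testing.assert_allclose(model(frame), loaded(frame), rtol=1e-6)
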