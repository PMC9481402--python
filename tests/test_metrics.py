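"""Confusion-matrix metrics under the AAMI conventions.

The reference fixture is the published inter-patient confusion matrix of
the ensemble classifier on the DS2 test set; its printed per-class and
overall summary values are frozen here as expected outputs.
"""

import numpy as np
import pytest

from beatvote.dataset import AAMI_CLASSES, AamiClass
from beatvote.metrics import (
    ConfusionMatrix5,
    build_confusion,
    classifier_table,
    compute_report,
    load_reference_base_table,
    overall_metrics,
    per_class_metrics,
    round_half_up,
)


def brute_force_overall(counts):
    """Independent re-derivation from the plain-prose definitions:
    TP: abnormal beats classified as their own abnormal class;
    TN: normal beats classified normal; FP: normal classified abnormal;
    FN: abnormal classified normal; Acc: all correct over all beats."""
    idx = {c: i for i, c in enumerate(AAMI_CLASSES)}
    n = idx[AamiClass.N]
    tp = tn = fp = fn = correct = 0
    for i in range(5):
        for j in range(5):
            c = int(counts[i, j])
            if i == j:
                correct += c
            if i == n and j == n:
                tn += c
            elif i == n and j != n:
                fp += c
            elif i != n and j == n:
                fn += c
            elif i == j:
                tp += c
    total = int(counts.sum())
    pct = lambda a, b: None if b == 0 else 100.0 * a / b
    return (
        pct(correct, total),
        pct(tp, tp + fp),
        pct(tp, tp + fn),
        pct(tn, tn + fp),
    )


class TestBuildConfusion:
    def test_empty_gives_zero_matrix(self):
        cm = build_confusion([])
        assert cm.counts.sum() == 0

    def test_single_pair_lands_in_true_row_predicted_column(self):
        cm = build_confusion([(AamiClass.S, AamiClass.V)])
        assert cm.counts[1, 2] == 1
        assert cm.counts.sum() == 1

    def test_reference_row_sums_match_test_set_composition(self, reference_confusion):
        sums = {
            cls: reference_confusion.row_sum(cls) for cls in AAMI_CLASSES
        }
        assert sums == {
            AamiClass.N: 44215,
            AamiClass.S: 1836,
            AamiClass.V: 3219,
            AamiClass.F: 388,
            AamiClass.Q: 7,
        }

    def test_permutation_invariance(self, rng):
        pairs = [
            (AAMI_CLASSES[i], AAMI_CLASSES[j])
            for i, j in rng.integers(0, 5, size=(200, 2))
        ]
        cm1 = build_confusion(pairs)
        perm = rng.permutation(len(pairs))
        cm2 = build_confusion([pairs[i] for i in perm])
        np.testing.assert_array_equal(cm1.counts, cm2.counts)


class TestPerClassMetrics:
    def test_reference_s_row(self, reference_confusion):
        m = per_class_metrics(reference_confusion, AamiClass.S)
        assert round_half_up(m.sen) == 80.23
        assert round_half_up(m.ppv) == 49.40
        assert round_half_up(m.spe) == 96.85

    def test_reference_v_row(self, reference_confusion):
        m = per_class_metrics(reference_confusion, AamiClass.V)
        assert round_half_up(m.sen) == 90.99
        assert round_half_up(m.ppv) == 83.09
        assert round_half_up(m.spe) == 98.72

    def test_reference_n_row(self, reference_confusion):
        m = per_class_metrics(reference_confusion, AamiClass.N)
        assert round_half_up(m.sen) == 93.15
        assert round_half_up(m.ppv) == 98.18
        assert round_half_up(m.spe) == 86.00

    def test_identity_matrix_is_perfect(self):
        cm = ConfusionMatrix5(np.diag([10, 10, 10, 10, 10]))
        for cls in AAMI_CLASSES:
            m = per_class_metrics(cm, cls)
            assert (m.sen, m.ppv, m.spe) == (100.0, 100.0, 100.0)

    def test_undefined_precision_is_none_not_zero(self, reference_confusion):
        # Q is never predicted in the reference matrix
        m = per_class_metrics(reference_confusion, AamiClass.Q)
        assert m.ppv is None
        assert m.sen == 0.0

    def test_tp_fn_fp_tn_partition_total(self, rng):
        counts = rng.integers(0, 50, size=(5, 5))
        cm = ConfusionMatrix5(counts)
        for cls in AAMI_CLASSES:
            i = AAMI_CLASSES.index(cls)
            tp = counts[i, i]
            fn = counts[i].sum() - tp
            fp = counts[:, i].sum() - tp
            tn = counts.sum() - tp - fn - fp
            assert tp + fn + fp + tn == cm.total


class TestOverallMetrics:
    def test_reference_summary(self, reference_confusion):
        o = overall_metrics(reference_confusion)
        assert round_half_up(o.acc) == 91.89
        assert round_half_up(o.ppv) == 59.51
        assert round_half_up(o.sen) == 85.37
        assert round_half_up(o.spe) == 93.15

    def test_all_normal_perfect_matrix(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 0] = 100
        o = overall_metrics(ConfusionMatrix5(counts))
        assert o.acc == 100.0
        assert o.spe == 100.0
        assert o.sen is None  # no abnormal beats at all
        assert o.ppv is None

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 200, size=(5, 5))
            o = overall_metrics(ConfusionMatrix5(counts))
            acc, ppv, sen, spe = brute_force_overall(counts)
            assert o.acc == acc
            assert o.ppv == ppv
            assert o.sen == sen
            assert o.spe == spe

    def test_overall_spe_equals_n_sensitivity(self, reference_confusion):
        o = overall_metrics(reference_confusion)
        n = per_class_metrics(reference_confusion, AamiClass.N)
        assert o.spe == pytest.approx(n.sen)

    def test_transposed_matrix_changes_sen_and_ppv(self, reference_confusion):
        o = overall_metrics(reference_confusion)
        ot = overall_metrics(ConfusionMatrix5(reference_confusion.counts.T))
        assert o.sen != ot.sen  # orientation matters
        assert o.ppv != ot.ppv


class TestClassifierTable:
    def test_reference_mean_row(self):
        table = classifier_table(load_reference_base_table().values.tolist())
        mean = table.loc["mean"]
        assert round_half_up(mean["acc"]) == 87.63
        assert round_half_up(mean["ppv"]) == 46.76
        assert round_half_up(mean["sen"]) == 84.19
        assert round_half_up(mean["spe"]) == 88.81

    def test_single_report_mean_is_itself(self):
        table = classifier_table([[90.0, 50.0, 80.0, 85.0]])
        assert table.loc["mean"].tolist() == [90.0, 50.0, 80.0, 85.0]


class TestSerialisation:
    def test_csv_round_trip(self, reference_confusion, tmp_path):
        path = tmp_path / "cm.csv"
        reference_confusion.to_csv(path)
        back = ConfusionMatrix5.from_csv(path)
        np.testing.assert_array_equal(back.counts, reference_confusion.counts)

    def test_report_json_contains_rounded_overall(self, reference_confusion):
        report = compute_report(reference_confusion)
        d = report.to_dict()
        assert d["overall"]["acc"] == 91.89
        assert d["per_class"]["Q"]["ppv"] is None

    def test_round_half_up_rounds_midpoints_up(self):
        assert round_half_up(87.625) == 87.63
        assert round_half_up(0.005) == 0.01
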