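import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pts1pred as pp
from pts1pred.evaluation import (
    ConfusionCounts,
    confusion_from_scores,
    format_sweep_table,
    round_half_away,
)
from pts1pred.seq_io import windows_from_records


def r3(x):
    return round_half_away(x, 3)


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "counts, acc, mcc",
        [
            ((75, 2, 174, 15), 0.936, 0.858),
            ((90, 175, 1, 0), 0.342, 0.044),
        ],
    )
    def test_published_style_confusions(self, counts, acc, mcc):
        rep = pp.compute_metrics(ConfusionCounts(*counts))
        assert r3(rep.accuracy) == acc
        assert r3(rep.mcc) == mcc

    def test_perfect_classifier(self):
        rep = pp.compute_metrics(ConfusionCounts(10, 0, 10, 0))
        assert (rep.accuracy, rep.sensitivity, rep.specificity, rep.mcc) == (1, 1, 1, 1)

    def test_zero_marginal_mcc_is_undefined_not_an_exception(self):
        rep = pp.compute_metrics(ConfusionCounts(tp=5, fp=5, tn=0, fn=0))
        assert not rep.mcc_defined
        assert math.isnan(rep.mcc)
        assert rep.format_value("mcc") == "N.A."
        no_negatives = pp.compute_metrics(ConfusionCounts(tp=5, fp=0, tn=0, fn=1))
        assert math.isnan(no_negatives.specificity)
        assert no_negatives.format_value("specificity") == "N.A."

    def test_empty_confusion_raises(self):
        with pytest.raises(ValueError):
            pp.compute_metrics(ConfusionCounts(0, 0, 0, 0))

    @settings(derandomize=True, max_examples=80)
    @given(
        tp=st.integers(0, 300), fp=st.integers(0, 300),
        tn=st.integers(0, 300), fn=st.integers(0, 300),
    )
    def test_accuracy_identity_and_mcc_symmetry(self, tp, fp, tn, fn):
        """Acc == (Sens*P + Spec*N)/(P+N); MCC invariant under TP<->TN, FP<->FN."""
        c = ConfusionCounts(tp, fp, tn, fn)
        if c.total == 0:
            return
        rep = pp.compute_metrics(c)
        if c.n_pos > 0 and c.n_neg > 0:
            assert rep.accuracy == pytest.approx(
                (rep.sensitivity * c.n_pos + rep.specificity * c.n_neg) / c.total,
                rel=1e-12,
            )
        swapped = pp.compute_metrics(ConfusionCounts(tn, fn, tp, fp))
        if rep.mcc_defined:
            assert swapped.mcc == pytest.approx(rep.mcc, rel=1e-12)
        else:
            assert not swapped.mcc_defined


class TestReconstructConfusion:
    @pytest.mark.parametrize(
        "sens, spec, P, N, expected",
        [
            (0.833, 0.987, 90, 176, (75, 2, 174, 15)),
            (1.0, 0.006, 90, 176, (90, 175, 1, 0)),
            (1.0, 1.0, 5, 5, (5, 0, 5, 0)),
        ],
    )
    def test_known_columns(self, sens, spec, P, N, expected):
        c = pp.reconstruct_confusion(sens, spec, P, N)
        assert (c.tp, c.fp, c.tn, c.fn) == expected

    @settings(derandomize=True, max_examples=80)
    @given(P=st.integers(1, 300), data=st.data())
    def test_inverts_three_decimal_printing(self, P, data):
        """Against the enumeration oracle: the TP minimising |TP/P - sens|."""
        tp = data.draw(st.integers(0, P))
        sens = round_half_away(tp / P, 3)
        oracle = min(range(P + 1), key=lambda t: (abs(t / P - sens), -t))
        c = pp.reconstruct_confusion(sens, 1.0, P, 10)
        assert c.tp == oracle
        assert c.tp + c.fn == P

    def test_out_of_range_inputs_raise(self):
        with pytest.raises(ValueError):
            pp.reconstruct_confusion(1.2, 0.5, 10, 10)
        with pytest.raises(ValueError):
            pp.reconstruct_confusion(0.5, 0.5, 0, 10)


class TestCutoffSweep:
    def test_threshold_monotonicity_on_cv_scores(self, synth_cv):
        sweep = synth_cv.sweep()
        assert len(sweep) == 7
        assert (np.diff(sweep.sensitivity) <= 1e-12).all()
        assert (np.diff(sweep.specificity) >= -1e-12).all()

    def test_cutoff_below_all_scores_calls_everything_positive(self):
        sweep = pp.cutoff_sweep([0.2, 0.9, 1.4], [1, -1, 1], cutoffs=[0.0])
        assert sweep.sensitivity.iloc[0] == 1.0
        assert sweep.specificity.iloc[0] == 0.0

    def test_empty_cutoff_list_raises(self):
        with pytest.raises(ValueError):
            pp.cutoff_sweep([1.0], [1], cutoffs=[])

    def test_formatted_table_mirrors_published_layout(self, synth_cv):
        text = format_sweep_table(synth_cv.sweep())
        lines = text.strip().splitlines()
        assert lines[0].startswith("Cut-off Value\t-1.5\t-1\t-0.5\t0\t0.5\t1\t1.5")
        assert [l.split("\t")[0] for l in lines[1:]] == [
            "Sensitivity", "Specificity", "Accuracy", "MCC",
        ]


class TestCrossValidate:
    def test_same_seed_reproduces_folds_and_report(self, synth_windows):
        pos, neg = synth_windows
        a = pp.cross_validate(pos, neg, k=5, C=8.0, gamma=0.125, seed=13)
        b = pp.cross_validate(pos, neg, k=5, C=8.0, gamma=0.125, seed=13)
        np.testing.assert_array_equal(a.scores, b.scores)
        assert a.pooled == b.pooled

    def test_profiles_are_fold_local(self, synth_windows):
        """Held-out scores must differ from train-on-everything scores:
        if profiles leaked the full data the two would coincide."""
        pos, neg = synth_windows
        cv = pp.cross_validate(pos, neg, k=5, C=8.0, gamma=0.125, seed=13)
        full = pp.train(pos, neg, C=8.0, gamma=0.125)
        from pts1pred.classifier import decision_scores

        full_scores = decision_scores(full, list(pos) + list(neg))
        assert not np.allclose(cv.scores, full_scores)

    def test_leave_one_out_per_class_pools_to_single_confusion(self):
        data = pp.generate_synthetic(pp.SyntheticSpec(n_pos=8, n_neg=8, seed=5))
        pos = windows_from_records(data.positives, 10)
        neg = windows_from_records(data.negatives, 10)
        cv = pp.cross_validate(pos, neg, k=8, cutoff=0.0, C=8.0, gamma=0.125, seed=5)
        assert cv.pooled.confusion.total == 16
        assert len(cv.folds) == 8

    def test_k_larger_than_class_raises(self, synth_windows):
        pos, neg = synth_windows
        with pytest.raises(ValueError):
            pp.cross_validate(pos[:3], neg, k=5)


def test_length_sweep_one_row_per_length():
    data = pp.generate_synthetic(pp.SyntheticSpec(n_pos=25, n_neg=50, seed=31))
    table = pp.length_sweep(
        data.positives, data.negatives, lengths=(3, 10, 30),
        k=3, cutoff=0.0, C=8.0, gamma=0.125, seed=31,
    )
    assert list(table.length) == [3, 10, 30]
    # L=3 sees only the tripeptide, which separates the classes by construction
    assert table.accuracy.iloc[0] > 0.9


def test_confusion_from_scores_counts():
    c = confusion_from_scores([1.2, 0.4, -0.5, 2.0], [1, -1, -1, -1], cutoff=1.0)
    assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 2, 0)
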