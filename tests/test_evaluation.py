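"""Voting, confusion arithmetic, ROC, t-test and Kjeldahl utilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nitrospec import (ConfusionMatrix, KjeldahlInput, SplitScheme, ccr,
                       confusion, kjeldahl_nitrogen, majority_vote,
                       misclassified_pct, paired_t_test, per_class_metrics,
                       roc_auc)

CLASSES = ("D0", "D1", "D2", "D3")


class TestMajorityVote:
    def _scores(self, n_voters, n, k=3):
        return [np.full((n, k), 1.0 / k) for _ in range(n_voters)]

    def test_strict_plurality(self):
        votes = [np.array([v]) for v in "AAABC"]
        out = majority_vote(votes, self._scores(5, 1), ("A", "B", "C"))
        assert list(out) == ["A"]

    def test_unanimity_ignores_scores(self):
        votes = [np.array(["B", "B"]) for _ in range(3)]
        scores = [np.array([[0.9, 0.1], [0.9, 0.1]])] * 3
        out = majority_vote(votes, scores, ("A", "B"))
        assert list(out) == ["B", "B"]

    def test_tie_broken_by_summed_score_then_class_order(self):
        # A and B tie 2-2; summed scores favour B (1.7 > 1.4)
        votes = [np.array([v]) for v in "AABBC"]
        scores = [np.array([[a, b, c]]) for a, b, c in
                  [(0.5, 0.2, 0.3), (0.4, 0.3, 0.3), (0.2, 0.5, 0.3),
                   (0.2, 0.4, 0.4), (0.1, 0.3, 0.6)]]
        total_a = 0.5 + 0.4 + 0.2 + 0.2 + 0.1
        total_b = 0.2 + 0.3 + 0.5 + 0.4 + 0.3
        assert (total_a, total_b) == pytest.approx((1.4, 1.7))
        out = majority_vote(votes, scores, ("A", "B", "C"))
        assert list(out) == ["B"]
        # equal summed scores fall back to class order
        out = majority_vote([np.array([v]) for v in "AABB"],
                            self._scores(4, 1), ("A", "B", "C"))
        assert list(out) == ["A"]

    def test_zero_voters_rejected(self):
        with pytest.raises(ValueError, match="voter"):
            majority_vote([], [], ("A",))


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        y = ["D0", "D1", "D2", "D3", "D1"]
        cm = confusion(y, y, CLASSES)
        assert np.trace(cm.counts) == 5 and cm.total == 5

    def test_empty_inputs_zero_matrix(self):
        cm = confusion([], [], CLASSES)
        assert cm.total == 0

    def test_hand_tally(self):
        actual = ["D0", "D0", "D1", "D1", "D2", "D3"]
        predicted = ["D0", "D1", "D1", "D3", "D2", "D1"]
        cm = confusion(actual, predicted, CLASSES)
        expected = [[1, 1, 0, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 1, 0, 0]]
        np.testing.assert_array_equal(cm.counts, expected)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion(["D9"], ["D0"], CLASSES)

    def test_pooling_adds_counts(self):
        a = confusion(["D0"], ["D0"], CLASSES)
        b = confusion(["D0"], ["D1"], CLASSES)
        assert (a + b).counts[0, 0] == 1 and (a + b).counts[0, 1] == 1


class TestMatrixMetrics:
    def test_ccr_of_diagonal_matrix_is_100(self):
        cm = ConfusionMatrix(np.diag([5, 3, 2, 7]), CLASSES)
        assert ccr(cm) == 100.0
        assert misclassified_pct(cm, "D0") == 0.0

    def test_ccr_zero_total_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ccr(ConfusionMatrix(np.zeros((4, 4), int), CLASSES))

    def test_misclassified_zero_diagonal_rejected(self):
        counts = np.diag([5, 3, 2, 7])
        counts[1, 1] = 0
        with pytest.raises(ValueError, match="diagonal"):
            misclassified_pct(ConfusionMatrix(counts, CLASSES), "D1")

    def test_study_orientation_transposes_standard(self):
        counts = np.array([[8, 2], [1, 9]])
        cm = ConfusionMatrix(counts, ("A", "B"))
        study = per_class_metrics(cm, convention="study")
        standard = per_class_metrics(cm, convention="standard")
        # study recall = diagonal / column total; standard = / row total
        assert study.loc["A", "recall"] == pytest.approx(100 * 8 / 9)
        assert standard.loc["A", "recall"] == pytest.approx(100 * 8 / 10)
        assert study.loc["A", "precision"] == pytest.approx(100 * 8 / 10)
        # F is the harmonic mean of the row's recall and precision
        r, p = study.loc["A", "recall"], study.loc["A", "precision"]
        assert study.loc["A", "f"] == pytest.approx(2 * r * p / (r + p))

    def test_zero_column_reports_zero_with_warning(self):
        counts = np.array([[5, 0], [3, 0]])
        cm = ConfusionMatrix(counts, ("A", "B"))
        with pytest.warns(UserWarning, match="recall"):
            table = per_class_metrics(cm)
        assert table.loc["B", "recall"] == 0.0


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        auc, _, _ = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_u_statistic_enumeration(self, rng):
        """AUC equals the Mann–Whitney U statistic over all positive ×
        negative pairs (ties counted half)."""
        scores = rng.integers(0, 5, size=8).astype(float)  # force ties
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        auc, _, _ = roc_auc(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        u = sum(1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg)
        assert auc == pytest.approx(u / (pos.size * neg.size), abs=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-5, 5), min_size=6, max_size=12))
    def test_invariant_under_monotone_transform(self, raw):
        # quantise so the affine transform below cannot merge near-ties
        scores = np.round(np.asarray(raw), 3)
        labels = (np.arange(scores.size) % 2).astype(bool)
        a1, _, _ = roc_auc(scores, labels)
        # 2x + 1 is strictly monotone and exact in floating point, so the
        # tie pattern is preserved bit-for-bit
        a2, _, _ = roc_auc(2.0 * scores + 1.0, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestPairedTTest:
    def test_identical_samples(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0 and res.df == 2

    def test_three_pair_hand_case(self):
        a, b = [3.0, 5.0, 4.0], [2.0, 4.5, 2.5]
        d = np.array(a) - np.array(b)  # [1, 0.5, 1.5]
        mean, sd = d.mean(), d.std(ddof=1)
        res = paired_t_test(a, b)
        assert res.mean_difference == pytest.approx(mean)
        assert res.t == pytest.approx(mean / (sd / np.sqrt(3)), abs=1e-12)
        assert res.df == 2

    def test_constant_nonzero_difference(self):
        res = paired_t_test([1.0, 2.0], [0.0, 1.0])
        assert np.isinf(res.t) and res.p == 0.0

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ValueError, match="equal length"):
            paired_t_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="two pairs"):
            paired_t_test([1.0], [2.0])


class TestKjeldahl:
    def test_blank_equals_sample_gives_zero(self):
        assert kjeldahl_nitrogen(KjeldahlInput(5.0, 5.0, 0.1, 1.0)) == 0.0

    def test_documented_example(self):
        value = kjeldahl_nitrogen(KjeldahlInput(10.0, 0.2, 0.1, 0.5))
        assert value == pytest.approx(2.744)

    def test_negative_difference_warns(self):
        with pytest.warns(UserWarning, match="blank"):
            out = kjeldahl_nitrogen(KjeldahlInput(0.1, 0.5, 0.1, 1.0))
        assert out < 0

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            kjeldahl_nitrogen(KjeldahlInput(5.0, 0.0, 0.1, 0.0))


def test_split_scheme_validation():
    SplitScheme().validate()
    with pytest.raises(ValueError, match="sum to 1"):
        SplitScheme(train=0.7, test=0.3, validation=0.1).validate()
    with pytest.raises(ValueError, match="iterations"):
        SplitScheme(iterations=0).validate()


def test_ccr_consistent_with_weighted_misclassification():
    """CCR computed as trace/total equals 100 minus the total off-diagonal
    share — the two bookkeeping routes of the same matrix agree."""
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 50, size=(4, 4))
    counts += np.diag(rng.integers(50, 200, size=4))
    cm = ConfusionMatrix(counts, CLASSES)
    off = counts.sum() - np.trace(counts)
    assert ccr(cm) == pytest.approx(100.0 * (1 - off / counts.sum()))
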