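"""Hanley AUROC machinery, threshold metrics, cut-offs, sample size."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepatexture.roc_stats import (auroc_hanley, best_cutoff, compare_auroc,
                                   hanley_se, sample_size_auroc, spearman,
                                   threshold_metrics)

from oracles import auc_pair_counting


def _exp_scores(rng, auc, n_pos, n_neg):
    """Scores under the negative-exponential ROC model with given AUROC."""
    rate_pos = (1 - auc) / auc
    scores = np.concatenate([rng.exponential(1 / rate_pos, n_pos),
                             rng.exponential(1.0, n_neg)])
    labels = np.concatenate([np.ones(n_pos), np.zeros(n_neg)]).astype(int)
    return scores, labels


class TestAUROC:
    def test_perfect_separation(self):
        r = auroc_hanley([3, 4, 5, 1, 2], [1, 1, 1, 0, 0])
        assert r.auroc == 1.0
        assert r.se == 0.0
        assert r.ci95 == (1.0, 1.0)

    def test_all_ties_give_half(self):
        r = auroc_hanley([1.0] * 10, [1] * 5 + [0] * 5)
        assert r.auroc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 8, 20).astype(float)  # forces ties
        labels = rng.integers(0, 2, 20)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        r = auroc_hanley(scores, labels)
        assert r.auroc == pytest.approx(
            auc_pair_counting(scores.tolist(), labels.tolist()), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores, labels = _exp_scores(rng, 0.8, 15, 15)
        a = auroc_hanley(scores, labels).auroc
        b = auroc_hanley(np.log1p(scores) * 7 - 2, labels).auroc
        assert a == pytest.approx(b, abs=1e-12)

    def test_label_flip_complements(self):
        rng = np.random.default_rng(2)
        scores, labels = _exp_scores(rng, 0.75, 12, 18)
        a = auroc_hanley(scores, labels).auroc
        b = auroc_hanley(scores, 1 - labels).auroc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc_hanley([1, 2, 3], [1, 1, 1])

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(3)
        scores, labels = _exp_scores(rng, 0.7, 20, 20)
        curve = auroc_hanley(scores, labels).curve
        assert np.all(np.diff(curve[:, 0]) >= 0)
        assert np.all(np.diff(curve[:, 1]) >= 0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 6), min_size=2, max_size=30),
       st.data())
def test_auroc_properties_hold_on_arbitrary_tied_scores(raw, data):
    """Pair-counting equality, label-flip complement and bounds hold for
    arbitrary integer (tie-heavy) score vectors."""
    n = len(raw)
    labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    if sum(labels) in (0, n):
        labels[0] = 1 - labels[0]
    scores = [float(v) for v in raw]
    r = auroc_hanley(scores, labels)
    assert 0.0 <= r.auroc <= 1.0
    assert r.auroc == pytest.approx(auc_pair_counting(scores, labels),
                                    abs=1e-12)
    flipped = auroc_hanley(scores, [1 - y for y in labels]).auroc
    assert r.auroc + flipped == pytest.approx(1.0, abs=1e-12)
    assert 0.0 <= r.ci95[0] <= r.auroc <= r.ci95[1] <= 1.0


class TestHanleySE:
    def test_se_shrinks_toward_perfect_auc(self):
        ses = [hanley_se(a, 30, 30) for a in (0.7, 0.8, 0.9, 0.99)]
        assert all(b < a for a, b in zip(ses, ses[1:]))
        assert hanley_se(1.0, 30, 30) == 0.0

    def test_se_shrinks_with_sample_size(self):
        ses = [hanley_se(0.8, n, n) for n in (10, 20, 50, 200)]
        assert all(b < a for a, b in zip(ses, ses[1:]))


class TestCompare:
    def test_identical_scores_give_zero_z(self):
        rng = np.random.default_rng(4)
        scores, labels = _exp_scores(rng, 0.8, 20, 20)
        z, p = compare_auroc(scores, scores, labels, paired=True)
        assert z == 0.0 and p == 1.0

    def test_length_mismatch_rejected_in_paired_mode(self):
        with pytest.raises(ValueError, match="equal-length"):
            compare_auroc([1, 2, 3], [1, 2], [1, 0, 1], paired=True)

    def test_unpaired_type_i_error_calibrated(self):
        # reduced replicate count here; the full 2000-rep check runs in
        # the acceptance suite
        rng = np.random.default_rng(5)
        rej = 0
        reps = 400
        for _ in range(reps):
            sa, la = _exp_scores(rng, 0.8, 50, 50)
            sb, lb = _exp_scores(rng, 0.8, 50, 50)
            _, p = compare_auroc(sa, sb, la, paired=False, labels_b=lb)
            rej += p < 0.05
        assert 0.02 <= rej / reps <= 0.08

    def test_power_consistent_with_sample_size_output(self):
        n = sample_size_auroc(0.83, 0.95, alpha=0.05, power=0.80,
                              prevalence=0.5)
        rng = np.random.default_rng(6)
        hits = 0
        reps = 2000
        m = n // 2
        for _ in range(reps):
            sa, la = _exp_scores(rng, 0.95, m, m)
            sb, lb = _exp_scores(rng, 0.83, m, m)
            _, p = compare_auroc(sa, sb, la, paired=False, labels_b=lb)
            hits += p < 0.05
        assert hits / reps == pytest.approx(0.80, abs=0.05)


class TestThresholdMetrics:
    def test_clean_separation_all_metrics_one(self):
        m = threshold_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1, 1, 1, 1)

    def test_all_below_threshold_degenerate(self):
        m = threshold_metrics([0.1, 0.2, 0.3], [1, 0, 1], 0.5)
        assert m.sensitivity == 0.0 and m.specificity == 1.0
        assert m.ppv is None and m.npv == pytest.approx(1 / 3)

    def test_counts_match_hand_tally_on_39_subjects(self):
        rng = np.random.default_rng(7)
        scores = rng.random(39)
        labels = (rng.random(39) < 0.5).astype(int)
        labels[0], labels[1] = 1, 0
        t = 0.5
        m = threshold_metrics(scores, labels, t)
        tp = sum(1 for s, y in zip(scores, labels) if s > t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s > t and y == 0)
        tn = sum(1 for s, y in zip(scores, labels) if s <= t and y == 0)
        fn = sum(1 for s, y in zip(scores, labels) if s <= t and y == 1)
        assert (m.tp, m.fp, m.tn, m.fn) == (tp, fp, tn, fn)
        assert m.tp + m.fp + m.tn + m.fn == 39

    def test_strictly_greater_rule_at_threshold(self):
        m = threshold_metrics([0.5, 0.6, 0.4], [1, 1, 0], 0.5)
        assert m.tp == 1 and m.fn == 1  # the score equal to t is negative


class TestBestCutoff:
    def test_separated_classes_gap_midpoint_nearest_half(self):
        t = best_cutoff([0.2, 0.3, 0.8, 0.9], [0, 0, 1, 1])
        assert t == pytest.approx(0.55)  # midpoint of the gap

    def test_youden_optimality_property(self):
        rng = np.random.default_rng(8)
        scores, labels = _exp_scores(rng, 0.85, 15, 15)
        t = best_cutoff(scores, labels)
        m = threshold_metrics(scores, labels, t)
        j_best = m.sensitivity + m.specificity - 1
        s = np.unique(scores)
        for cand in (s[:-1] + s[1:]) / 2:
            mc = threshold_metrics(scores, labels, cand)
            assert mc.sensitivity + mc.specificity - 1 <= j_best + 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(24)
        labels = rng.integers(0, 2, 24)
        if labels.sum() in (0, 24):
            labels[0] = 1 - labels[0]
        t = best_cutoff(scores, labels)
        m = threshold_metrics(scores, labels, t)
        j = m.sensitivity + m.specificity - 1
        s = np.sort(np.unique(scores))
        best = max(
            (threshold_metrics(scores, labels, c).sensitivity
             + threshold_metrics(scores, labels, c).specificity - 1)
            for c in (s[:-1] + s[1:]) / 2)
        assert j == pytest.approx(best, abs=1e-12)


class TestSampleSize:
    def test_reference_computation_is_finite_and_reported(self):
        n = sample_size_auroc(0.83, 0.95, alpha=0.05, power=0.80,
                              prevalence=0.5)
        assert isinstance(n, int) and 4 < n < 1000

    def test_wider_gap_needs_fewer_subjects(self):
        n_narrow = sample_size_auroc(0.83, 0.90)
        n_wide = sample_size_auroc(0.83, 0.97)
        assert n_wide < n_narrow

    def test_equal_aucs_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            sample_size_auroc(0.8, 0.8)


class TestSpearman:
    def test_identical_and_reversed(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_matches_rank_formula(self):
        rng = np.random.default_rng(9)
        x, y = rng.random(25), rng.random(25)
        rho, _ = spearman(x, y)
        # brute force: Pearson correlation of midranks
        def ranks(v):
            order = sorted(range(len(v)), key=lambda i: v[i])
            r = [0.0] * len(v)
            for pos, i in enumerate(order):
                r[i] = pos + 1.0
            return r
        rx, ry = ranks(list(x)), ranks(list(y))
        mx, my = np.mean(rx), np.mean(ry)
        num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
        den = np.sqrt(sum((a - mx) ** 2 for a in rx)
                      * sum((b - my) ** 2 for b in ry))
        assert rho == pytest.approx(num / den, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
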