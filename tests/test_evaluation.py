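"""ROC/PR statistics, matched-specificity thresholds, DeLong, phrase rules."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asyncecg.evaluation import (
    CRITERION_1_PHRASES,
    CRITERION_2_PHRASES,
    SingleClassError,
    categorize_interpretation,
    delong_test,
    placement_values,
    roc_pr,
    sensitivity_at_specificity,
)


def mann_whitney_auc(scores, labels):
    """Brute-force pairwise oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocPr:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        res = roc_pr(scores, labels)
        assert res.auroc == 1.0
        assert res.auprc == 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, size=4000)
        assert roc_pr(scores, labels).auroc == pytest.approx(0.5, abs=0.03)

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(4, 21))
            labels = np.zeros(n, int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = rng.integers(0, 5, size=n).astype(float)  # forces ties
            assert roc_pr(scores, labels).auroc == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12
            )

    def test_curve_endpoints_and_monotone_fpr(self):
        rng = np.random.default_rng(2)
        res = roc_pr(rng.normal(size=100), rng.integers(0, 2, 100))
        assert tuple(res.roc_points[0]) == (0.0, 0.0)
        assert tuple(res.roc_points[-1]) == (1.0, 1.0)
        assert np.all(np.diff(res.roc_points[:, 0]) >= 0)

    def test_confusion_conservation(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        res = roc_pr(rng.normal(size=50), y)
        assert np.all(res.confusion.sum(axis=1) == 50)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            roc_pr(np.array([0.1, 0.9]), np.array([1, 1]))

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_auroc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a = roc_pr(scores, labels).auroc
        b = roc_pr(np.exp(2 * scores) + 1, labels).auroc
        assert a == pytest.approx(b, abs=1e-12)


def brute_force_operating_point(scores, labels, target):
    """Exhaustive threshold scan oracle."""
    best = None
    for t in np.append(np.unique(scores), np.inf):
        pred = scores >= t
        tn = np.sum(~pred & (labels == 0))
        spec = tn / np.sum(labels == 0)
        if spec < target:
            continue
        sens = np.sum(pred & (labels == 1)) / np.sum(labels == 1)
        if best is None or sens > best[0]:
            best = (sens, spec, t)
    return best


class TestMatchedSpecificity:
    def test_scores_equal_labels(self):
        y = np.array([0, 0, 0, 1, 1])
        op = sensitivity_at_specificity(y.astype(float), y, 0.866)
        assert op.sensitivity == 1.0
        assert op.specificity == 1.0

    def test_matches_exhaustive_scan(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.9, 0.5, 0.3, 0.2, 0.7])
        labels = np.array([0, 0, 1, 1, 0, 1, 0, 0, 0, 1])
        for target in (0.3, 0.5, 0.7, 0.866):
            op = sensitivity_at_specificity(scores, labels, target)
            sens, spec, thr = brute_force_operating_point(scores, labels, target)
            assert op.sensitivity == pytest.approx(sens)
            assert op.specificity == pytest.approx(spec)
            assert op.specificity >= target

    def test_sensitivity_monotone_in_target(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=200) + rng.integers(0, 2, 200)
        labels = (scores + rng.normal(size=200) > 0.5).astype(int)
        op_low = sensitivity_at_specificity(scores, labels, 0.647)
        op_high = sensitivity_at_specificity(scores, labels, 0.866)
        assert op_low.sensitivity >= op_high.sensitivity

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_at_specificity(np.array([0.1, 0.9]), np.array([0, 1]), 1.5)


def delong_variance_by_hand(sa, sb, y):
    """Structural components written out with explicit loops."""
    pos_a = sa[y == 1]; neg_a = sa[y == 0]
    pos_b = sb[y == 1]; neg_b = sb[y == 0]
    m, n = len(pos_a), len(neg_a)

    def psi(x, yv):
        return 1.0 if x > yv else (0.5 if x == yv else 0.0)

    v10a = np.array([np.mean([psi(p, q) for q in neg_a]) for p in pos_a])
    v01a = np.array([np.mean([psi(p, q) for p in pos_a]) for q in neg_a])
    v10b = np.array([np.mean([psi(p, q) for q in neg_b]) for p in pos_b])
    v01b = np.array([np.mean([psi(p, q) for p in pos_b]) for q in neg_b])
    s10 = np.cov(np.stack([v10a, v10b]))
    s01 = np.cov(np.stack([v01a, v01b]))
    return (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        cmp = delong_test(s, s, y)
        assert cmp.z == 0.0
        assert cmp.p_value == 1.0

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(6)
        sa, sb = rng.normal(size=(2, 60))
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        ab = delong_test(sa, sb, y)
        ba = delong_test(sb, sa, y)
        assert ab.p_value == pytest.approx(ba.p_value)
        assert ab.z == pytest.approx(-ba.z)

    def test_variance_matches_hand_computation(self):
        rng = np.random.default_rng(7)
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        sa = rng.normal(size=12) + y
        sb = rng.normal(size=12) + 0.5 * y
        cmp = delong_test(sa, sb, y)
        assert cmp.var_diff == pytest.approx(
            delong_variance_by_hand(sa, sb, y), rel=1e-10
        )
        v10, v01, auc = placement_values(sa, y)
        assert auc == pytest.approx(mann_whitney_auc(sa, y))
        assert np.mean(v10) == pytest.approx(auc)
        assert np.mean(v01) == pytest.approx(auc)

    def test_p_value_agrees_with_paired_bootstrap(self):
        rng = np.random.default_rng(8)
        n_pos, n_neg = 40, 80
        y = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
        latent = rng.normal(size=n_pos + n_neg) + 1.2 * y
        sa = latent + rng.normal(scale=0.8, size=len(y))
        sb = latent + rng.normal(scale=1.3, size=len(y))
        cmp = delong_test(sa, sb, y)

        def auc(scores, labels):
            v, _, a = placement_values(scores, labels)
            return a

        diffs = np.empty(10_000)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        for i in range(10_000):
            take = np.r_[
                rng.choice(pos_idx, n_pos, replace=True),
                rng.choice(neg_idx, n_neg, replace=True),
            ]
            diffs[i] = auc(sa[take], y[take]) - auc(sb[take], y[take])
        boot_p = 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())
        assert cmp.p_value == pytest.approx(boot_p, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            delong_test(np.zeros(3), np.ones(3), np.ones(3, int))


FIXTURE_CORPUS = [
    "ACUTE MI",
    "Possible anterior infarct, age undetermined",
    "ST elevation, consider acute injury",
    "ST depression, possible subendocardial injury",
    "T wave abnormality, consider lateral ischemia",
    "ST abnormality, nonspecific",
    "Normal sinus rhythm",
    "Sinus tachycardia with nonspecific changes",
    "acute mi suspected",  # case-insensitive match
    "ST   elevation with extra   spacing",
    "",
]


class TestInterpretation:
    def test_quoted_phrase_examples(self):
        assert categorize_interpretation("ACUTE MI", 1)
        assert not categorize_interpretation("ST depression", 1)
        assert categorize_interpretation("ST depression", 2)
        assert not categorize_interpretation("", 1)
        assert not categorize_interpretation("", 2)

    def test_criterion2_superset_on_corpus(self):
        pos1 = {t for t in FIXTURE_CORPUS if categorize_interpretation(t, 1)}
        pos2 = {t for t in FIXTURE_CORPUS if categorize_interpretation(t, 2)}
        assert pos1 <= pos2
        assert "ST depression, possible subendocardial injury" in pos2 - pos1

    def test_phrase_sets_nested(self):
        assert set(CRITERION_1_PHRASES) < set(CRITERION_2_PHRASES)

    def test_whitespace_and_case_robustness(self):
        assert categorize_interpretation("st   ELEVATION noted", 1)

    def test_invalid_criterion_rejected(self):
        with pytest.raises(ValueError):
            categorize_interpretation("ACUTE MI", 3)

    @settings(deadline=None, derandomize=True)
    @given(st.text(max_size=60), st.sampled_from(CRITERION_2_PHRASES))
    def test_superset_property_random_text(self, prefix, phrase):
        text = prefix + phrase
        if categorize_interpretation(text, 1):
            assert categorize_interpretation(text, 2)
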