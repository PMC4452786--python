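"""ROC/AUC oracle checks, operating points, and the experiment harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fundusbovw import compute_roc, confusion_metrics, operating_point
from fundusbovw.errors import InvalidInputError, ProtocolViolationError, UndefinedROCError


def mann_whitney_auc(scores, labels):
    """Brute-force pair-counting statistic (ties count one half)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        roc = compute_roc([1, 2, 3, 10, 11], [False, False, False, True, True])
        assert roc.auc == 1.0

    def test_all_scores_tied(self):
        roc = compute_roc([5.0] * 8, [True, False] * 4)
        assert roc.auc == 0.5

    def test_twelve_mixed_scores_match_pair_counting(self, rng):
        scores = rng.integers(0, 6, size=12).astype(float)  # force ties
        labels = np.array([True] * 5 + [False] * 7)
        roc = compute_roc(scores, labels)
        assert roc.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        labels[0] = True
        labels[1] = False
        roc = compute_roc(scores, labels)
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
        assert (np.diff(roc.thresholds) <= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedROCError):
            compute_roc([1.0, 2.0], [True, True])


class TestOperatingPoint:
    def test_zero_target_gives_full_sensitivity(self, rng):
        roc = compute_roc(rng.normal(size=30), rng.random(30) < 0.5)
        sens, _ = operating_point(roc, 0.0)
        assert sens == 1.0

    def test_full_target_on_separable_scores(self):
        roc = compute_roc([0, 1, 2, 10, 11, 12], [False] * 3 + [True] * 3)
        sens, _ = operating_point(roc, 1.0)
        assert sens == 1.0

    def test_matches_exhaustive_threshold_search(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        labels[:2] = [True, False]
        roc = compute_roc(scores, labels)
        target = 0.9
        # oracle: sweep every candidate threshold directly
        best = (-1.0, -1.0)
        for t in np.concatenate([[np.inf], np.unique(scores)[::-1]]):
            flags = scores >= t
            tp = (flags & labels).sum()
            tn = (~flags & ~labels).sum()
            sens = tp / labels.sum()
            spec = tn / (~labels).sum()
            if spec >= target:
                best = max(best, (sens, spec))
        sens, _ = operating_point(roc, target)
        assert sens == pytest.approx(best[0], abs=1e-12)


class TestConfusion:
    def test_perfect_and_inverted(self):
        labels = np.array([True, True, False, False])
        m = confusion_metrics(labels, labels)
        assert (m.sensitivity, m.specificity, m.accuracy) == (1.0, 1.0, 1.0)
        m = confusion_metrics(~labels, labels)
        assert (m.sensitivity, m.specificity, m.accuracy) == (0.0, 0.0, 0.0)

    def test_screening_shaped_counts(self):
        """18 normals / 12 abnormals with 16 TN, 2 FP, 9 TP, 3 FN."""
        labels = np.array([False] * 18 + [True] * 12)
        flags = np.array([False] * 16 + [True] * 2 + [True] * 9 + [False] * 3)
        m = confusion_metrics(flags, labels)
        assert (m.tn, m.fp, m.tp, m.fn) == (16, 2, 9, 3)
        assert m.specificity == pytest.approx(16 / 18)
        assert m.sensitivity == pytest.approx(0.75)

    def test_undefined_rates_are_none_not_zero(self):
        m = confusion_metrics([False, True], [False, False])
        assert m.sensitivity is None and m.specificity == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            confusion_metrics([True], [True, False])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(5, 200))
def test_auc_equals_mann_whitney_property(seed, n):
    """Trapezoidal AUC with tie-grouping == pair-counting statistic."""
    rng = np.random.default_rng(seed)
    scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
    labels = rng.random(n) < rng.uniform(0.2, 0.8)
    if labels.all() or (~labels).all():
        labels[0] = ~labels[0]
    roc = compute_roc(scores, labels)
    assert roc.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)


@pytest.fixture(scope="module")
def within_report(cohort_pair_dirs):
    from fundusbovw import run_within_cohort
    from conftest import small_run_config

    return run_within_cohort(
        cohort_pair_dirs["fix-a"] / "manifest.csv", small_run_config(), split_seed=2
    )


class TestHarness:
    def test_within_cohort_separable_aucs(self, within_report):
        """Held-out split of the strongly-lesioned fixture is near-separable."""
        assert within_report.per_detector["bright"]["auc"] >= 0.95
        assert within_report.per_detector["red"]["auc"] >= 0.95

    def test_train_test_isolation_audited(self, within_report):
        assert not set(within_report.train_ids) & set(within_report.test_ids)

    def test_multilesion_subsets_reported(self, within_report):
        t1 = within_report.multi_lesion["test1"]
        t2 = within_report.multi_lesion["test2"]
        assert t1["n_pos"] >= t2["n_pos"]
        # test 2 compares normals against dual-lesion images only
        assert t2["n_pos"] == 3  # 6 'both' images -> 3 held out
        for entry in (t1, t2):
            c = entry["confusion"]
            assert c["tp"] + c["fn"] == entry["n_pos"]
            assert c["tn"] + c["fp"] == entry["n_neg"]

    def test_cross_dataset_rejects_overlap(self, cohort_pair_dirs):
        from fundusbovw import run_cross_dataset
        from conftest import small_run_config

        manifest = cohort_pair_dirs["fix-a"] / "manifest.csv"
        with pytest.raises(ProtocolViolationError):
            run_cross_dataset(manifest, manifest, small_run_config())
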