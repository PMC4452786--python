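"""Decision models: separability, determinism, fusion semantics."""

import numpy as np
import pytest

from fundusbovw import (
    compute_roc,
    fuse,
    fuse_score,
    score,
    standardized_score,
    train_detector,
)
from fundusbovw.decision import load_model, save_model, screen
from fundusbovw.errors import InsufficientDataError, InvalidInputError
from fundusbovw.midlevel import BoVWHistogram


def toy_histograms(rng, n_pos=20, n_neg=20, k=6):
    """Positives concentrated on word 0, negatives on word 1, plus noise."""
    X, y = [], []
    for i in range(n_pos + n_neg):
        h = 0.05 * rng.random(k)
        h[0 if i < n_pos else 1] += 1.0
        X.append(h / np.linalg.norm(h))
        y.append(i < n_pos)
    return np.array(X), np.array(y)


class TestTrainDetector:
    def test_separable_training_accuracy(self, rng):
        X, y = toy_histograms(rng)
        model = train_detector(X, y, lesion="bright")
        preds = np.array([score(model, x) for x in X]) > 0
        assert (preds == y).all()

    def test_deterministic_given_seed(self, rng):
        X, y = toy_histograms(rng)
        probe = rng.random((5, 6))
        m1 = train_detector(X, y, lesion="red", seed=3)
        m2 = train_detector(X, y, lesion="red", seed=3)
        assert np.array_equal(m1.weights, m2.weights) and m1.bias == m2.bias
        assert [score(m1, p) for p in probe] == [score(m2, p) for p in probe]

    def test_label_flip_mirrors_auc(self, rng):
        """Flipping the labels of a fixed 40-image set maps AUC to 1 - AUC."""
        X, y = toy_histograms(rng, n_pos=20, n_neg=20)
        X = X + 0.3 * rng.random(X.shape)  # make it imperfectly separable
        m = train_detector(X, y, lesion="bright", seed=0)
        m_flip = train_detector(X, ~y, lesion="bright", seed=0)
        s = np.array([score(m, x) for x in X])
        s_flip = np.array([score(m_flip, x) for x in X])
        auc = compute_roc(s, y).auc
        auc_flip = compute_roc(s_flip, y).auc
        assert auc_flip == pytest.approx(1.0 - auc, abs=0.02)

    def test_single_class_rejected(self, rng):
        X, _ = toy_histograms(rng)
        with pytest.raises(InsufficientDataError):
            train_detector(X, np.ones(len(X), bool), lesion="bright")
        with pytest.raises(InsufficientDataError):
            train_detector(X[:3], [True, False, False], lesion="red")


class TestScore:
    def test_zero_histogram_scores_bias(self, rng):
        X, y = toy_histograms(rng)
        m = train_detector(X, y, lesion="bright")
        assert score(m, np.zeros(6)) == pytest.approx(m.bias)

    def test_linear_interpolation_monotone(self, rng):
        X, y = toy_histograms(rng)
        m = train_detector(X, y, lesion="bright")
        neg, pos = X[~y][0], X[y][0]
        scores = [score(m, (1 - t) * neg + t * pos) for t in np.linspace(0, 1, 11)]
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_dimension_mismatch_rejected(self, rng):
        X, y = toy_histograms(rng)
        m = train_detector(X, y, lesion="bright")
        with pytest.raises(InvalidInputError):
            score(m, np.zeros(9))

    def test_standardized_score_centres_training_normals(self, rng):
        X, y = toy_histograms(rng)
        m = train_detector(X, y, lesion="bright")
        std = [standardized_score(m, x) for x in X[~y]]
        assert np.median(std) == pytest.approx(0.0, abs=1e-12)


class TestFusion:
    @pytest.mark.parametrize("fb,fr,expected", [
        (False, False, False),
        (False, True, True),
        (True, False, True),
        (True, True, True),
    ])
    def test_truth_table(self, fb, fr, expected):
        """Normal only when both detectors agree it is normal."""
        assert fuse(fb, fr) is expected

    def test_fuse_score_is_max(self):
        assert fuse_score(-1.0, -2.0) == -1.0
        assert fuse_score(0.5, 2.5) == 2.5

    def test_threshold_equivalence_with_or(self, rng):
        """fuse_score > t iff (bright > t) OR (red > t), any threshold."""
        for _ in range(200):
            sb, sr = rng.normal(size=2)
            t = rng.normal()
            assert (fuse_score(sb, sr) > t) == fuse(sb > t, sr > t)


class TestPersistenceAndScreen:
    def test_model_roundtrip_bit_exact(self, tmp_path, rng):
        X, y = toy_histograms(rng)
        m = train_detector(X, y, lesion="red", codebook_ref="cbref1")
        path = tmp_path / "model.json"
        save_model(m, path, config_hash="cfg")
        loaded, config_hash = load_model(path)
        assert config_hash == "cfg"
        assert np.array_equal(loaded.weights, m.weights)
        assert (loaded.bias, loaded.threshold, loaded.normal_score_median) == (
            m.bias, m.threshold, m.normal_score_median
        )
        assert loaded.lesion == "red" and loaded.codebook_ref == "cbref1"

    def test_screen_flags_follow_thresholds(self, rng):
        Xb, yb = toy_histograms(rng)
        Xr, yr = toy_histograms(rng)
        mb = train_detector(Xb, yb, lesion="bright")
        mr = train_detector(Xr, yr, lesion="red")

        def hist(image_id, counts, ref):
            return BoVWHistogram(image_id=image_id, counts=counts, normalized="l2",
                                 codebook_ref=ref, n_pois=10)

        hb = [hist(f"i{j}", Xb[j], "b") for j in range(6)]
        hr = [hist(f"i{j}", Xr[j], "r") for j in range(6)]
        results = screen(mb, mr, hb, hr)
        for j, r in enumerate(results):
            assert r.flag_bright == (r.score_bright > mb.threshold)
            assert r.flag_red == (r.score_red > mr.threshold)
            assert r.referable == (r.flag_bright or r.flag_red)
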