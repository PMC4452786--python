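"""Per-lesion decision models and the multi-lesion fusion rule.

Each lesion family (bright, red) gets its own binary scorer: a regularised
maximum-margin linear classifier (linear SVM) on BoVW histograms, trained
with that lesion's images as positives and normal images as negatives.
The score of an image is its signed distance to the separating boundary;
the default operating threshold is 0 (the margin boundary).

For screening, the two detectors are fused with a deliberately
conservative rule: an image is called normal only when *both* detectors
call it normal — i.e. ``referable = flag_bright OR flag_red`` — which
minimises false negatives.  For a threshold sweep of the fused system a
continuous combined score is needed; we use the maximum of the two scores
after standardising each to zero median on the training normals (the raw
scales of two independently trained SVMs are not comparable).
Thresholding that max at ``t`` is exactly the OR of the per-detector
flags at ``t``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import LinearSVC

from .errors import FormatError, InsufficientDataError, InvalidInputError
from .midlevel import BoVWHistogram


@dataclass
class DecisionModel:
    lesion: str                 # "bright" | "red"
    weights: np.ndarray         # (k,)
    bias: float
    threshold: float = 0.0
    normal_score_median: float = 0.0
    codebook_ref: str = ""
    training_meta: str = ""

    @property
    def k(self) -> int:
        return len(self.weights)


@dataclass
class ScreeningResult:
    image_id: str
    score_bright: float
    score_red: float
    flag_bright: bool
    flag_red: bool

    @property
    def referable(self) -> bool:
        return self.flag_bright or self.flag_red


def _counts_matrix(histograms) -> np.ndarray:
    rows = [h.counts if isinstance(h, BoVWHistogram) else np.asarray(h, float) for h in histograms]
    return np.stack(rows)


def train_detector(
    histograms,
    labels,
    lesion: str,
    C: float = 1.0,
    seed: int = 0,
    codebook_ref: str = "",
) -> DecisionModel:
    """Fit the linear max-margin scorer for one lesion family.

    ``labels`` are booleans (lesion present).  Requires at least two
    examples of each class.  The fit is deterministic given the data and
    seed.  The median raw score of the negative (normal) training images
    is stored for later score standardisation.
    """
    X = _counts_matrix(histograms)
    y = np.asarray(labels, dtype=bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise InsufficientDataError(
            f"need >=2 examples per class, got {int(y.sum())} positive / {int((~y).sum())} negative"
        )
    clf = LinearSVC(
        C=C, loss="squared_hinge", dual="auto", tol=1e-6, max_iter=50_000,
        random_state=seed,
    )
    clf.fit(X, y.astype(int))
    weights = clf.coef_.ravel().astype(float)
    bias = float(clf.intercept_[0])
    raw_neg = X[~y] @ weights + bias
    return DecisionModel(
        lesion=lesion,
        weights=weights,
        bias=bias,
        threshold=0.0,
        normal_score_median=float(np.median(raw_neg)),
        codebook_ref=codebook_ref,
        training_meta=f"n_pos={int(y.sum())} n_neg={int((~y).sum())} C={C} seed={seed}",
    )


def score(model: DecisionModel, histogram) -> float:
    """Signed distance to the boundary; a zero histogram scores the bias."""
    x = histogram.counts if isinstance(histogram, BoVWHistogram) else np.asarray(histogram, float)
    if x.shape != (model.k,):
        raise InvalidInputError(f"histogram of shape {x.shape} does not match model k={model.k}")
    return float(x @ model.weights + model.bias)


def standardized_score(model: DecisionModel, histogram) -> float:
    """Raw score shifted to zero median on the training normals."""
    return score(model, histogram) - model.normal_score_median


def fuse(flag_bright: bool, flag_red: bool) -> bool:
    """Normal only if both detectors agree it is normal (logical OR)."""
    return bool(flag_bright) or bool(flag_red)


def fuse_score(score_bright: float, score_red: float) -> float:
    """Continuous multi-lesion score: max of the two standardised scores."""
    return max(float(score_bright), float(score_red))


def screen(
    model_bright: DecisionModel,
    model_red: DecisionModel,
    histograms_bright,
    histograms_red,
) -> list[ScreeningResult]:
    """Score paired per-codebook histograms of the same image sequence."""
    results = []
    for hb, hr in zip(histograms_bright, histograms_red, strict=True):
        if hb.image_id != hr.image_id:
            raise InvalidInputError(
                f"histogram pairing mismatch: {hb.image_id} vs {hr.image_id}"
            )
        sb = score(model_bright, hb)
        sr = score(model_red, hr)
        results.append(
            ScreeningResult(
                image_id=hb.image_id,
                score_bright=sb,
                score_red=sr,
                flag_bright=sb > model_bright.threshold,
                flag_red=sr > model_red.threshold,
            )
        )
    return results


# ---------------------------------------------------------------------------
# persistence


def save_model(model: DecisionModel, path, config_hash: str = "") -> None:
    payload = {
        "format": "fundusbovw model v1",
        "lesion": model.lesion,
        "weights": list(model.weights),
        "bias": model.bias,
        "threshold": model.threshold,
        "normal_score_median": model.normal_score_median,
        "codebook_ref": model.codebook_ref,
        "training_meta": model.training_meta,
        "config_hash": config_hash,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_model(path) -> tuple[DecisionModel, str]:
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "fundusbovw model v1":
        raise FormatError(f"{path}: not a fundusbovw model file")
    for key in ("lesion", "weights", "bias", "threshold", "normal_score_median"):
        if key not in payload:
            raise FormatError(f"{path}: model file missing field '{key}'")
    return (
        DecisionModel(
            lesion=payload["lesion"],
            weights=np.array(payload["weights"], dtype=float),
            bias=float(payload["bias"]),
            threshold=float(payload["threshold"]),
            normal_score_median=float(payload["normal_score_median"]),
            codebook_ref=payload.get("codebook_ref", ""),
            training_meta=payload.get("training_meta", ""),
        ),
        payload.get("config_hash", ""),
    )


def save_screening(results: list[ScreeningResult], path) -> None:
    """CSV: id,score_bright,score_red,flag_bright,flag_red,referable."""
    with open(path, "w") as fh:
        fh.write("id,score_bright,score_red,flag_bright,flag_red,referable\n")
        for r in results:
            fh.write(
                f"{r.image_id},{r.score_bright:.17g},{r.score_red:.17g},"
                f"{int(r.flag_bright)},{int(r.flag_red)},{int(r.referable)}\n"
            )
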