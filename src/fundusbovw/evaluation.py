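"""ROC/AUC evaluation and the cross-dataset experiment harness.

Conventions: sensitivity is the true-positive rate among lesion images,
specificity the true-negative rate among normals.  ROC curves are traced
by sweeping the decision threshold over the distinct score values (tied
scores form one step), with the two degenerate endpoints included; AUC is
the trapezoidal area, which equals the Mann-Whitney pair statistic with
ties counted one half.

The harness implements the cross-dataset protocol — codebooks and
decision models are fitted on one cohort and evaluated on a disjoint
cohort — plus a within-cohort mode using a seeded stratified 50/50 split.
Per-detector ROCs compare that lesion's images against normals; the fused
multi-lesion system is evaluated both on the full test set ("test 1") and
on the normals-versus-dual-lesion subset ("test 2").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InvalidInputError, ProtocolViolationError, UndefinedROCError
from .io import RunConfig, load_manifest, load_rois, read_image
from .pipeline import ScreeningPipeline
from .synthetic import LabeledImage


@dataclass
class ROCCurve:
    """Threshold sweep: points ordered by threshold descending."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist(), self.thresholds.tolist()))

    def to_dict(self) -> dict:
        return {
            "fpr": self.fpr.tolist(),
            "tpr": self.tpr.tolist(),
            # JSON has no +/-inf; the endpoint thresholds are stored as strings
            "thresholds": [
                float(t) if np.isfinite(t) else ("inf" if t > 0 else "-inf")
                for t in self.thresholds
            ],
            "auc": self.auc,
        }


@dataclass
class ConfusionMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def compute_roc(scores, labels) -> ROCCurve:
    """ROC by threshold sweep over the distinct scores; trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise InvalidInputError("scores and labels must be equal-length 1-D vectors")
    if labels.all() or (~labels).all():
        raise UndefinedROCError("ROC undefined: only one class present")
    fpr, tpr, thr = _sk_roc_curve(labels.astype(int), scores, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_trapezoid_auc(fpr, tpr)))


def operating_point(roc: ROCCurve, target_specificity: float) -> tuple[float, float]:
    """Best sensitivity subject to specificity >= target.

    Among feasible thresholds the one maximising sensitivity is returned;
    sensitivity ties resolve toward higher specificity.  The degenerate
    endpoints make every target in [0, 1] feasible.
    """
    spec = 1.0 - roc.fpr
    feasible = spec >= target_specificity - 1e-12
    idx = np.nonzero(feasible)[0]
    best = max(idx, key=lambda i: (roc.tpr[i], spec[i]))
    return float(roc.tpr[best]), float(roc.thresholds[best])


def confusion_metrics(flags, labels) -> ConfusionMetrics:
    """Confusion-matrix ratios; zero-denominator ratios come back as None."""
    flags = np.asarray(flags, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if flags.shape != labels.shape:
        raise InvalidInputError(
            f"flags ({flags.shape}) and labels ({labels.shape}) differ in length"
        )
    tp = int((flags & labels).sum())
    tn = int((~flags & ~labels).sum())
    fp = int((flags & ~labels).sum())
    fn = int((~flags & labels).sum())
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    acc = (tp + tn) / (tp + tn + fp + fn) if (tp + tn + fp + fn) else None
    return ConfusionMetrics(tp=tp, tn=tn, fp=fp, fn=fn,
                            sensitivity=sens, specificity=spec, accuracy=acc)


@dataclass
class EvaluationReport:
    experiment: dict
    per_detector: dict = dataclass_field(default_factory=dict)
    multi_lesion: dict = dataclass_field(default_factory=dict)
    train_ids: list[str] = dataclass_field(default_factory=list)
    test_ids: list[str] = dataclass_field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "per_detector": self.per_detector,
            "multi_lesion": self.multi_lesion,
            "train_ids": self.train_ids,
            "test_ids": self.test_ids,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, indent=1, allow_nan=False)
            fh.write("\n")


def load_cohort_images(manifest_path, with_rois: bool = False) -> list[LabeledImage]:
    """Materialise a manifest into labelled images (optionally with ROIs)."""
    manifest_path = Path(manifest_path)
    df = load_manifest(manifest_path)
    images = []
    for row in df.itertuples(index=False):
        img = LabeledImage(
            image=read_image(row.abs_path),
            label_bright=bool(row.label_bright),
            label_red=bool(row.label_red),
            cohort=row.cohort,
            id=row.id,
        )
        if with_rois and (img.label_bright or img.label_red):
            img.rois = load_rois(manifest_path.parent, row.id)
        images.append(img)
    return images


def _evaluate_on(
    pipe: ScreeningPipeline,
    test_images: list[LabeledImage],
    config: RunConfig,
    experiment: dict,
) -> EvaluationReport:
    results = pipe.screen(test_images)
    std = pipe.standardized_scores(results)
    is_normal = np.array(
        [not (i.label_bright or i.label_red) for i in test_images], dtype=bool
    )
    report = EvaluationReport(
        experiment={**experiment, "config_hash": config.config_hash},
        train_ids=sorted(pipe.training_ids),
        test_ids=sorted(i.id for i in test_images),
    )

    raw_scores = {
        "bright": np.array([r.score_bright for r in results]),
        "red": np.array([r.score_red for r in results]),
    }
    labels = {
        "bright": np.array([i.label_bright for i in test_images], dtype=bool),
        "red": np.array([i.label_red for i in test_images], dtype=bool),
    }
    for lesion in ("bright", "red"):
        sel = labels[lesion] | is_normal  # this lesion's images vs normals
        entry: dict = {
            "n_pos": int(labels[lesion][sel].sum()),
            "n_neg": int(is_normal[sel].sum()),
        }
        try:
            roc = compute_roc(raw_scores[lesion][sel], labels[lesion][sel])
            sens, thr = operating_point(roc, config.target_specificity)
            entry.update(
                auc=roc.auc,
                roc=roc.to_dict(),
                operating_points=[
                    {
                        "target_specificity": config.target_specificity,
                        "sensitivity": sens,
                        # the all-negative endpoint has an infinite threshold
                        "threshold": thr if np.isfinite(thr)
                        else ("inf" if thr > 0 else "-inf"),
                    }
                ],
            )
        except UndefinedROCError:
            entry["auc"] = None
        flags = raw_scores[lesion][sel] > pipe.models[lesion].threshold
        entry["confusion"] = confusion_metrics(flags, labels[lesion][sel]).to_dict()
        report.per_detector[lesion] = entry

    referable = np.array([r.referable for r in results], dtype=bool)
    fused = np.maximum(std[:, 0], std[:, 1])
    abnormal = ~is_normal
    dual = labels["bright"] & labels["red"]
    for name, sel in (("test1", np.ones(len(results), dtype=bool)), ("test2", is_normal | dual)):
        entry = {
            "n_pos": int(abnormal[sel].sum()),
            "n_neg": int(is_normal[sel].sum()),
            "confusion": confusion_metrics(referable[sel], abnormal[sel]).to_dict(),
        }
        try:
            roc = compute_roc(fused[sel], abnormal[sel])
            entry["auc"] = roc.auc
            entry["roc"] = roc.to_dict()
        except UndefinedROCError:
            entry["auc"] = None
        report.multi_lesion[name] = entry
    return report


def evaluate_cross_dataset_images(
    train_images: list[LabeledImage],
    test_images: list[LabeledImage],
    config: RunConfig,
) -> EvaluationReport:
    """In-memory cross-dataset protocol over already-materialised cohorts."""
    train_cohorts = {i.cohort for i in train_images}
    test_cohorts = {i.cohort for i in test_images}
    if train_cohorts & test_cohorts:
        raise ProtocolViolationError(
            f"train and test cohorts overlap: {sorted(train_cohorts & test_cohorts)}"
        )
    overlap = {i.id for i in train_images} & {i.id for i in test_images}
    if overlap:
        raise ProtocolViolationError(f"image ids present in both cohorts: {sorted(overlap)[:5]}")
    pipe = ScreeningPipeline(config).fit(train_images)
    return _evaluate_on(
        pipe,
        test_images,
        config,
        {
            "protocol": "cross-dataset",
            "train_cohort": ",".join(sorted(train_cohorts)),
            "test_cohort": ",".join(sorted(test_cohorts)),
            "seed": config.seed,
        },
    )


def run_cross_dataset(train_manifest, test_manifest, config: RunConfig) -> EvaluationReport:
    """Fit on one cohort manifest, evaluate on a disjoint cohort manifest.

    Raises :class:`ProtocolViolationError` if the cohorts share a name or
    any image id; the report records every train and test id so the
    isolation can be audited after the fact.
    """
    train_images = load_cohort_images(train_manifest, with_rois=True)
    test_images = load_cohort_images(test_manifest, with_rois=False)
    return evaluate_cross_dataset_images(train_images, test_images, config)


def run_within_cohort(manifest, config: RunConfig, split_seed: int = 0) -> EvaluationReport:
    """Within-cohort mode: seeded stratified 50/50 split of one cohort."""
    images = load_cohort_images(manifest, with_rois=True)
    rng = np.random.default_rng(split_seed)
    strata: dict[tuple[bool, bool], list[int]] = {}
    for idx, img in enumerate(images):
        strata.setdefault((img.label_bright, img.label_red), []).append(idx)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for key in sorted(strata):
        members = np.array(strata[key])
        perm = rng.permutation(len(members))
        half = (len(members) + 1) // 2
        train_idx.extend(members[perm[:half]])
        test_idx.extend(members[perm[half:]])
    train_images = [images[i] for i in sorted(train_idx)]
    test_images = [images[i] for i in sorted(test_idx)]
    pipe = ScreeningPipeline(config).fit(train_images)
    return _evaluate_on(
        pipe,
        test_images,
        config,
        {
            "protocol": "within-cohort",
            "train_cohort": images[0].cohort if images else "",
            "test_cohort": images[0].cohort if images else "",
            "seed": config.seed,
            "split_seed": split_seed,
        },
    )


def save_roc_csv(roc: ROCCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr,tpr,threshold\n")
        for f, t, th in roc.points:
            fh.write(f"{f:.17g},{t:.17g},{th:.17g}\n")


def plot_roc(curves: dict[str, ROCCurve], path) -> None:
    """Optional ROC figure (one curve per labelled system)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, roc in curves.items():
        ax.plot(roc.fpr, roc.tpr, label=f"{name} (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate (1 - specificity)")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
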