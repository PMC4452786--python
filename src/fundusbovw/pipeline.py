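"""End-to-end screening pipeline: features -> codebooks -> detectors.

`ScreeningPipeline.fit` consumes labelled training images (with ROI masks
on the lesion images) and produces, per lesion family, a visual codebook
and a trained decision model:

* codebook descriptors are sampled from two classes — the lesion's
  ROI-restricted PoIs ("positive") and whole-image PoIs of normal images
  ("negative") — and clustered (or randomly selected) into k words;
* the decision model is trained on whole-image histograms, positives being
  the images carrying that lesion and negatives the normal images (images
  carrying only the *other* lesion take part in neither detector's
  training, matching a normal-vs-lesion design).

`ScreeningPipeline.screen` encodes unseen images against both codebooks
and returns per-image scores and flags.  The ids of every image used in
fitting are recorded so a cross-dataset protocol can audit train/test
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import codebook as cb
from . import decision, lowlevel, midlevel
from .errors import InsufficientDataError
from .io import RunConfig
from .synthetic import LabeledImage

LESIONS = ("bright", "red")

# fixed per-stage seed offsets derived from the run seed
_SEED_OFFSETS = {"bright": 101, "red": 202}


def _label(img: LabeledImage, lesion: str) -> bool:
    return img.label_bright if lesion == "bright" else img.label_red


@dataclass
class ScreeningPipeline:
    config: RunConfig
    codebooks: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    training_ids: list[str] = field(default_factory=list)
    _poi_cache: dict = field(default_factory=dict, repr=False)

    def _detect(self, img: LabeledImage) -> lowlevel.DescriptorSet:
        if img.id not in self._poi_cache:
            self._poi_cache[img.id] = lowlevel.detect_pois(
                img.image, self.config.detector_config(), image_id=img.id
            )
        return self._poi_cache[img.id]

    def fit(self, images: list[LabeledImage]) -> "ScreeningPipeline":
        self.training_ids = [img.id for img in images]
        normals = [img for img in images if not img.label_bright and not img.label_red]
        if not normals:
            raise InsufficientDataError("training set has no normal images")

        neg_sets = [self._detect(img) for img in normals]
        for lesion in LESIONS:
            positives = [img for img in images if _label(img, lesion)]
            if len(positives) < 2:
                raise InsufficientDataError(
                    f"training set has {len(positives)} {lesion}-lesion images; need >= 2"
                )
            pos_sets = [
                lowlevel.restrict_to_rois(
                    self._detect(img), img.masks_of_kind(lesion), mode="inside"
                )
                for img in positives
            ]
            seed = (self.config.seed + _SEED_OFFSETS[lesion]) & 0x7FFFFFFF
            pool = cb.sample_descriptors(
                {"positive": pos_sets, "negative": neg_sets},
                per_class_quota=self.config.per_class_quota,
                seed=seed,
            )
            if self.config.codebook_provenance == "kmeans":
                book = cb.learn_codebook_kmeans(
                    pool,
                    k=self.config.k,
                    seed=seed,
                    max_iter=self.config.kmeans_max_iter,
                    tol=self.config.kmeans_tol,
                )
            else:
                book = cb.learn_codebook_random(pool, k=self.config.k, seed=seed)
            self.codebooks[lesion] = book

            train_imgs = positives + normals
            hists = [
                midlevel.encode(self._detect(img), book, self.config.normalization)
                for img in train_imgs
            ]
            labels = [True] * len(positives) + [False] * len(normals)
            model = decision.train_detector(
                hists,
                labels,
                lesion=lesion,
                C=self.config.svm_c,
                seed=seed,
                codebook_ref=book.ref,
            )
            model.threshold = self.config.decision_threshold
            self.models[lesion] = model
        return self

    def encode_image(self, img: LabeledImage, lesion: str) -> midlevel.BoVWHistogram:
        return midlevel.encode(
            self._detect(img), self.codebooks[lesion], self.config.normalization
        )

    def screen(self, images: list[LabeledImage]) -> list[decision.ScreeningResult]:
        hb = [self.encode_image(img, "bright") for img in images]
        hr = [self.encode_image(img, "red") for img in images]
        return decision.screen(self.models["bright"], self.models["red"], hb, hr)

    def standardized_scores(self, results: list[decision.ScreeningResult]) -> np.ndarray:
        """(n, 2) array of median-centred (bright, red) scores."""
        mb = self.models["bright"].normal_score_median
        mr = self.models["red"].normal_score_median
        return np.array([[r.score_bright - mb, r.score_red - mr] for r in results])
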