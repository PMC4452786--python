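"""Mid-level encoding: hard assignment and sum pooling.

Each descriptor is assigned fully and only to its nearest visual word
(Euclidean distance, ties broken by the lowest word index), and the
assignments are sum-pooled into a k-bin activation histogram — the
bag-of-visual-words representation of the image.  A normalisation
(``none`` | ``l1`` | ``l2``) may then be applied; ``l2`` is the default
used before the margin classifier.

Images with zero PoIs encode to the all-zero vector and are flagged so
the decision stage can fall back to its bias term instead of failing.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .codebook import Codebook
from .errors import FormatError, InvalidInputError
from .lowlevel import DescriptorSet

NORMALIZATIONS = ("none", "l1", "l2")


@dataclass
class BoVWHistogram:
    image_id: str
    counts: np.ndarray
    normalized: str
    codebook_ref: str
    n_pois: int

    @property
    def empty(self) -> bool:
        return self.n_pois == 0


def hard_assign(descriptor: np.ndarray, codebook: Codebook) -> int:
    """Index of the nearest visual word; ties go to the lowest index."""
    descriptor = np.asarray(descriptor, dtype=float)
    if descriptor.shape != (codebook.dim,):
        raise InvalidInputError(
            f"descriptor of length {descriptor.shape} does not match codebook dim {codebook.dim}"
        )
    d2 = ((codebook.words - descriptor[None, :]) ** 2).sum(1)
    return int(np.argmin(d2))


def encode(dset: DescriptorSet, codebook: Codebook, normalization: str = "l2") -> BoVWHistogram:
    """Sum-pool the hard assignments of a descriptor set into a histogram."""
    if normalization not in NORMALIZATIONS:
        raise InvalidInputError(f"unknown normalization {normalization!r}")
    n = len(dset)
    counts = np.zeros(codebook.k)
    if n > 0:
        mat = dset.descriptor_matrix
        if mat.shape[1] != codebook.dim:
            raise InvalidInputError(
                f"descriptor dim {mat.shape[1]} does not match codebook dim {codebook.dim}"
            )
        d2 = (
            (mat**2).sum(1)[:, None]
            - 2.0 * mat @ codebook.words.T
            + (codebook.words**2).sum(1)[None, :]
        )
        labels = np.argmin(d2, axis=1)
        counts = np.bincount(labels, minlength=codebook.k).astype(float)
        if normalization == "l1":
            counts = counts / counts.sum()
        elif normalization == "l2":
            counts = counts / np.linalg.norm(counts)
    return BoVWHistogram(
        image_id=dset.image_id,
        counts=counts,
        normalized=normalization,
        codebook_ref=codebook.ref,
        n_pois=n,
    )


# ---------------------------------------------------------------------------
# persistence: CSV of histograms + JSON sidecar with provenance


def save_histograms(hists: list[BoVWHistogram], path, config_hash: str = "") -> None:
    path = Path(path)
    if not hists:
        raise InvalidInputError("no histograms to save")
    k = len(hists[0].counts)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "n_pois"] + [f"w{i}" for i in range(k)])
        for h in hists:
            writer.writerow([h.image_id, h.n_pois] + [f"{v:.17g}" for v in h.counts])
    sidecar = {
        "codebook_ref": hists[0].codebook_ref,
        "normalization": hists[0].normalized,
        "k": k,
        "config_hash": config_hash,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_histograms(path) -> tuple[list[BoVWHistogram], dict]:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"{sidecar_path}: histogram sidecar missing")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    hists = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        k = len(header) - 2
        if k != sidecar.get("k"):
            raise FormatError(f"{path}: column count {k} disagrees with sidecar k={sidecar.get('k')}")
        for row in reader:
            hists.append(
                BoVWHistogram(
                    image_id=row[0],
                    counts=np.array([float(v) for v in row[2:]]),
                    normalized=sidecar["normalization"],
                    codebook_ref=sidecar["codebook_ref"],
                    n_pois=int(row[1]),
                )
            )
    return hists, sidecar
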