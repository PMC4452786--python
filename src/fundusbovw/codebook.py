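"""Visual-codebook learning.

A codebook is an ordered list of k centroid descriptors ("visual words").
It can be learned by Lloyd's k-means with Euclidean distance over a
per-class sample of training descriptors, or by plain random selection.
Word order is fixed at creation and must survive save/load, because the
encoding stage addresses histogram bins by word index.

One codebook is built *per lesion detector*, from that lesion's
ROI-restricted positive descriptors plus descriptors from control images,
so each dictionary contains words for both the lesion appearance and the
normal retinal background.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import kmeans_plusplus

from .errors import FormatError, InsufficientDataError, InvalidInputError
from .lowlevel import DescriptorSet


@dataclass
class Codebook:
    words: np.ndarray              # (k, D), row order is the word index
    provenance: str                # "kmeans" | "random"
    seed: int
    training_meta: str = ""
    inertia_history: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.words.shape[0]

    @property
    def dim(self) -> int:
        return self.words.shape[1]

    @property
    def ref(self) -> str:
        """Content hash identifying this codebook in downstream artifacts."""
        h = hashlib.sha256()
        h.update(self.words.tobytes())
        h.update(f"{self.provenance}|{self.seed}".encode())
        return h.hexdigest()[:12]


def sample_descriptors(
    sets_by_class: Mapping[str, Sequence[DescriptorSet]],
    per_class_quota: int,
    seed: int,
) -> np.ndarray:
    """Uniform per-class subsample (without replacement) of descriptors.

    Classes are processed in sorted name order so the pool is deterministic
    in ``seed`` regardless of mapping order; each class contributes
    ``min(per_class_quota, available)`` rows.
    """
    rng = np.random.default_rng(seed)
    pools = []
    for cls in sorted(sets_by_class):
        mats = [d.descriptor_matrix for d in sets_by_class[cls] if len(d) > 0]
        if not mats:
            continue
        stacked = np.vstack(mats)
        n = stacked.shape[0]
        if n > per_class_quota:
            idx = rng.choice(n, size=per_class_quota, replace=False)
            stacked = stacked[np.sort(idx)]
        pools.append(stacked)
    if not pools:
        raise InsufficientDataError("no descriptors available to sample from")
    return np.vstack(pools)


def _assign(pool: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centre labels and squared distances (ties -> lowest index)."""
    d2 = (
        (pool**2).sum(1)[:, None]
        - 2.0 * pool @ centers.T
        + (centers**2).sum(1)[None, :]
    )
    np.maximum(d2, 0.0, out=d2)
    labels = np.argmin(d2, axis=1)
    return labels, d2[np.arange(len(pool)), labels]


def learn_codebook_kmeans(
    pool: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> Codebook:
    """Lloyd's algorithm with k-means++ seeding and Euclidean distance.

    Iterates until total centroid movement falls below ``tol`` or
    ``max_iter`` is reached.  Clusters that go empty are re-seeded with
    the point currently farthest from its assigned centroid, which cannot
    increase the objective.  The within-cluster inertia recorded after
    each assignment step is kept on the returned codebook so monotonic
    descent can be audited.
    """
    pool = np.asarray(pool, dtype=float)
    if pool.ndim != 2:
        raise InvalidInputError("descriptor pool must be a 2-D array")
    if pool.shape[0] < k:
        raise InsufficientDataError(f"pool of {pool.shape[0]} descriptors < k={k}")

    centers, _ = kmeans_plusplus(pool, n_clusters=k, random_state=seed)
    centers = centers.astype(float)
    inertia_history: list[float] = []
    for _ in range(max_iter):
        labels, mind2 = _assign(pool, centers)
        inertia_history.append(float(mind2.sum()))
        new_centers = centers.copy()
        counts = np.bincount(labels, minlength=k)
        for j in range(k):
            if counts[j] > 0:
                new_centers[j] = pool[labels == j].mean(axis=0)
        for j in np.nonzero(counts == 0)[0]:
            far = int(np.argmax(mind2))
            new_centers[j] = pool[far]
            mind2[far] = 0.0
        movement = float(np.linalg.norm(new_centers - centers, axis=1).sum())
        centers = new_centers
        if movement < tol:
            break
    return Codebook(
        words=centers,
        provenance="kmeans",
        seed=seed,
        training_meta=f"n_pool={pool.shape[0]} max_iter={max_iter} tol={tol}",
        inertia_history=inertia_history,
    )


def learn_codebook_random(pool: np.ndarray, k: int, seed: int = 0) -> Codebook:
    """Pick k pool descriptors uniformly without replacement as the words."""
    pool = np.asarray(pool, dtype=float)
    if pool.shape[0] < k:
        raise InsufficientDataError(f"pool of {pool.shape[0]} descriptors < k={k}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(pool.shape[0], size=k, replace=False))
    return Codebook(
        words=pool[idx].copy(),
        provenance="random",
        seed=seed,
        training_meta=f"n_pool={pool.shape[0]}",
    )


def save_codebook(cb: Codebook, path, config_hash: str = "") -> None:
    """Text container: header line, then k rows of D full-precision values."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"# fundusbovw codebook v1 k={cb.k} dim={cb.dim} "
            f"provenance={cb.provenance} seed={cb.seed} config_hash={config_hash}\n"
        )
        if cb.training_meta:
            fh.write(f"# meta {cb.training_meta}\n")
        for row in cb.words:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def load_codebook(path) -> tuple[Codebook, str]:
    """Load a codebook; round-trips words, k, seed and provenance exactly."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# fundusbovw codebook"):
            raise FormatError(f"{path}: missing codebook header")
        fields = dict(
            tok.split("=", 1) for tok in header.split() if "=" in tok
        )
        for key in ("k", "dim", "provenance", "seed"):
            if key not in fields:
                raise FormatError(f"{path}: header missing field '{key}'")
        k, dim = int(fields["k"]), int(fields["dim"])
        meta = ""
        rows = []
        for line in fh:
            if line.startswith("# meta "):
                meta = line[len("# meta "):].rstrip("\n")
                continue
            if line.startswith("#") or not line.strip():
                continue
            vals = line.split()
            if len(vals) != dim:
                raise FormatError(f"{path}: row with {len(vals)} values, expected dim={dim}")
            rows.append([float(v) for v in vals])
        if len(rows) != k:
            raise FormatError(f"{path}: found {len(rows)} words, header says k={k}")
    return (
        Codebook(
            words=np.array(rows),
            provenance=fields["provenance"],
            seed=int(fields["seed"]),
            training_meta=meta,
        ),
        fields.get("config_hash", ""),
    )
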