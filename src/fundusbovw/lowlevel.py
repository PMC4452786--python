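"""Point-of-interest detection and description.

The detector is a multi-scale determinant-of-Hessian (DoH) blob detector
run on the luminance projection of the colour image, which suits the
blob-like structures screening cares about (exudate deposits, dot/blot
haemorrhages, the optic disc, vessel junctions).  Each surviving
scale-space maximum is described by a gradient-orientation histogram over
a 4 x 4 grid of cells around the keypoint (4 orientation bins per cell,
64 dimensions), optionally extended with the Gaussian-weighted per-channel
colour means of the patch (3 extra dimensions) since lesions are as much a
colour event as a shape event.  No rotation invariance is applied: fundus
photographs are acquired upright.

All coordinates are 0-based with ``x`` the column and ``y`` the row;
sub-pixel positions are allowed and rounded half-up when indexing masks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, maximum_filter

from .errors import FormatError, InvalidInputError

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class DetectorConfig:
    """Detector/descriptor knobs; ``descriptor_dim`` is fixed per config."""

    n_scales: int = 5
    sigma0: float = 1.6
    scale_step: float = 1.6
    response_threshold: float = 1e-5
    max_pois: int = 500
    include_color: bool = True
    grid_cells: int = 4          # spatial cells per axis
    samples_per_cell: int = 4    # gradient samples per cell per axis
    orientation_bins: int = 4
    sample_spacing: float = 0.8  # sample step, in units of the PoI scale

    @property
    def descriptor_dim(self) -> int:
        d = self.grid_cells * self.grid_cells * self.orientation_bins
        return d + 3 if self.include_color else d

    @property
    def sigmas(self) -> tuple[float, ...]:
        return tuple(self.sigma0 * self.scale_step**i for i in range(self.n_scales))


@dataclass
class PointOfInterest:
    x: float
    y: float
    scale: float
    response: float
    descriptor: np.ndarray


@dataclass
class DescriptorSet:
    """Ordered PoIs of one image (response descending, ties by (y, x))."""

    image_id: str
    pois: list[PointOfInterest] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pois)

    @property
    def descriptor_matrix(self) -> np.ndarray:
        if not self.pois:
            dim = 0
            return np.empty((0, dim))
        return np.stack([p.descriptor for p in self.pois])


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidInputError(f"expected an HxWx3 image, got shape {image.shape}")
    if image.min() < -1e-9 or image.max() > 1 + 1e-9:
        raise InvalidInputError("image values must lie in [0, 1]")
    return image


def _sample_grid(config: DetectorConfig, sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-scale sampling offsets, Gaussian weights and cell indices."""
    n = config.grid_cells * config.samples_per_cell
    offs = (np.arange(n) - (n - 1) / 2.0) * config.sample_spacing * sigma
    u, v = np.meshgrid(offs, offs)           # u: x offset, v: y offset
    u, v = u.ravel(), v.ravel()
    sigma_w = 0.5 * offs.max() if offs.max() > 0 else 1.0
    weights = np.exp(-0.5 * (u**2 + v**2) / sigma_w**2)
    idx = np.arange(n * n)
    cell = (idx // n // config.samples_per_cell) * config.grid_cells + (
        idx % n
    ) // config.samples_per_cell
    return u, v, weights, cell


def detect_pois(image: np.ndarray, config: DetectorConfig | None = None,
                image_id: str = "") -> DescriptorSet:
    """Detect and describe blob-like points of interest.

    Scale-normalised DoH responses (``sigma^4 det H``) are computed on the
    luminance channel over a geometric scale ladder; 3x3x3 scale-space
    maxima above ``response_threshold`` become PoIs, capped at
    ``max_pois`` by response rank.  Determinism: identical image + config
    give an identical, identically ordered :class:`DescriptorSet`.
    """
    config = config or DetectorConfig()
    image = _validate_image(image)
    lum = image @ _LUMA
    h, w = lum.shape
    sigmas = config.sigmas

    # one smoothing pass per scale; Gaussian derivatives follow by central
    # finite differences of the smoothed image
    resp = np.empty((len(sigmas), h, w))
    grads = []
    for i, s in enumerate(sigmas):
        smoothed = gaussian_filter(lum, s)
        gy, gx = np.gradient(smoothed)
        gyy, gyx = np.gradient(gy)
        gxy, gxx = np.gradient(gx)
        resp[i] = s**4 * (gxx * gyy - gxy * gyx)
        grads.append((gx, gy))

    local_max = maximum_filter(resp, size=3, mode="nearest")
    cand = (resp >= local_max) & (resp > config.response_threshold)
    cand[:, :2, :] = cand[:, -2:, :] = False
    cand[:, :, :2] = cand[:, :, -2:] = False

    si, yi, xi = np.nonzero(cand)
    responses = resp[si, yi, xi]
    order = np.lexsort((xi, yi, -responses))
    si, yi, xi, responses = si[order], yi[order], xi[order], responses[order]
    if len(si) > config.max_pois:
        si, yi, xi = si[: config.max_pois], yi[: config.max_pois], xi[: config.max_pois]
        responses = responses[: config.max_pois]

    n_cells = config.grid_cells * config.grid_cells
    dim = config.descriptor_dim
    descriptors = np.zeros((len(si), dim))
    for scale_idx in range(len(sigmas)):
        sel = np.nonzero(si == scale_idx)[0]
        if sel.size == 0:
            continue
        s = sigmas[scale_idx]
        gx_img, gy_img = grads[scale_idx]
        u, v, wts, cell = _sample_grid(config, s)
        rows = yi[sel, None] + v[None, :]
        cols = xi[sel, None] + u[None, :]
        coords = [rows.ravel(), cols.ravel()]
        gx = map_coordinates(gx_img, coords, order=1, mode="nearest").reshape(sel.size, -1)
        gy = map_coordinates(gy_img, coords, order=1, mode="nearest").reshape(sel.size, -1)
        mag = np.hypot(gx, gy) * wts[None, :]
        theta = np.arctan2(gy, gx)
        obin = np.floor((theta + np.pi) / (2 * np.pi / config.orientation_bins)).astype(int)
        obin = np.clip(obin, 0, config.orientation_bins - 1)
        flat = cell[None, :] * config.orientation_bins + obin
        hist = np.zeros((sel.size, n_cells * config.orientation_bins))
        np.add.at(hist, (np.arange(sel.size)[:, None], flat), mag)
        norms = np.linalg.norm(hist, axis=1, keepdims=True)
        norms[norms < 1e-12] = 1.0
        hist /= norms
        descriptors[sel, : hist.shape[1]] = hist
        if config.include_color:
            wsum = wts.sum()
            for c in range(3):
                ch = map_coordinates(image[:, :, c], coords, order=1, mode="nearest")
                ch = ch.reshape(sel.size, -1)
                descriptors[sel, hist.shape[1] + c] = (ch * wts[None, :]).sum(1) / wsum

    pois = [
        PointOfInterest(
            x=float(xi[j]), y=float(yi[j]), scale=float(sigmas[si[j]]),
            response=float(responses[j]), descriptor=descriptors[j],
        )
        for j in range(len(si))
    ]
    return DescriptorSet(image_id=image_id, pois=pois)


def restrict_to_rois(dset: DescriptorSet, roi_masks, mode: str = "inside") -> DescriptorSet:
    """Keep PoIs whose rounded position falls inside (or outside) the mask union.

    Control images need no region marking and are passed through whole by
    callers; this filter is for lesion-class training images.  Together the
    ``inside`` and ``outside`` selections partition the input set.
    """
    if mode not in ("inside", "outside"):
        raise InvalidInputError(f"mode must be 'inside' or 'outside', got {mode!r}")
    masks = [np.asarray(m, dtype=bool) for m in roi_masks]
    if masks:
        shape = masks[0].shape
        if any(m.shape != shape for m in masks):
            raise InvalidInputError("ROI masks have inconsistent shapes")
        union = np.zeros(shape, dtype=bool)
        for m in masks:
            union |= m
    else:
        union = None

    kept = []
    for p in dset.pois:
        if union is None:
            inside = False
        else:
            iy = int(np.floor(p.y + 0.5))
            ix = int(np.floor(p.x + 0.5))
            if not (0 <= iy < union.shape[0] and 0 <= ix < union.shape[1]):
                raise InvalidInputError(
                    f"PoI at ({p.x}, {p.y}) falls outside the {union.shape} masks"
                )
            inside = bool(union[iy, ix])
        if inside == (mode == "inside"):
            kept.append(p)
    return DescriptorSet(image_id=dset.image_id, pois=kept)


# ---------------------------------------------------------------------------
# persistence: one CSV row per PoI


def save_descriptor_sets(dsets: list[DescriptorSet], path, config_hash: str = "") -> None:
    path = Path(path)
    dim = None
    for d in dsets:
        for p in d.pois:
            dim = len(p.descriptor)
            break
        if dim is not None:
            break
    dim = dim or 0
    with open(path, "w", newline="") as fh:
        fh.write(f"# fundusbovw descriptors v1 dim={dim} config_hash={config_hash}\n")
        writer = csv.writer(fh)
        writer.writerow(["image_id", "x", "y", "scale", "response"] + [f"d{i}" for i in range(dim)])
        for dset in dsets:
            for p in dset.pois:
                writer.writerow(
                    [dset.image_id, f"{p.x:.17g}", f"{p.y:.17g}", f"{p.scale:.17g}",
                     f"{p.response:.17g}"] + [f"{v:.17g}" for v in p.descriptor]
                )


def load_descriptor_sets(path) -> tuple[list[DescriptorSet], str]:
    """Load descriptor sets; returns (sets in file order, config hash)."""
    path = Path(path)
    with open(path, newline="") as fh:
        header = fh.readline()
        if not header.startswith("# fundusbovw descriptors"):
            raise FormatError(f"{path}: missing descriptor-file header")
        config_hash = ""
        for tok in header.split():
            if tok.startswith("config_hash="):
                config_hash = tok.split("=", 1)[1]
        reader = csv.reader(fh)
        cols = next(reader)
        dim = len(cols) - 5
        by_image: dict[str, DescriptorSet] = {}
        order: list[str] = []
        for row in reader:
            if len(row) != len(cols):
                raise FormatError(f"{path}: row with {len(row)} fields, expected {len(cols)}")
            image_id = row[0]
            if image_id not in by_image:
                by_image[image_id] = DescriptorSet(image_id=image_id)
                order.append(image_id)
            by_image[image_id].pois.append(
                PointOfInterest(
                    x=float(row[1]), y=float(row[2]), scale=float(row[3]),
                    response=float(row[4]),
                    descriptor=np.array([float(v) for v in row[5 : 5 + dim]]),
                )
            )
    return [by_image[i] for i in order], config_hash
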