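"""Synthetic retinal fundus cohorts with lesion ground truth.

This module generates labelled stand-ins for the two kinds of image sets a
fundus screening pipeline is trained and tested on: a training cohort from
one camera/site and a test cohort from another.  Each image is a circular
retina-like field (reddish-orange base, darker curvilinear vessels, a
brighter optic disc) on a dark surround.  Lesions are smooth elliptical
blobs:

* **bright lesions** (hard-exudate-like): positive intensity offsets
  concentrated in the red and green channels, giving yellowish deposits;
* **red lesions** (microaneurysm / dot-blot-haemorrhage-like): negative
  offsets that suppress mainly green and blue, giving small dark-red dots
  and larger blots.

Every lesion instance carries a binary region-of-interest (ROI) mask, the
synthetic analogue of specialist-marked lesion regions, so that downstream
codebook learning can sample descriptors from inside lesions only.

Cohort-level *domain shift* — the difference between two cameras and
populations — is modelled as the composition of (a) a different image
resolution, (b) per-channel colour gains, and (c) an optional JPEG
re-encoding at a configurable quality.  Nothing else differs between
cohorts, which keeps the cross-dataset experiment interpretable.

Lesion radii are specified in pixels at a reference image height of 480
lines and scaled linearly with the actual height, so that the same
``LesionSpec`` describes anatomically comparable lesions in cohorts of
different resolution.

Determinism: a cohort is a pure function of its ``CohortConfig``.  Image
``i`` of a cohort derives its seed as ``seed + i`` (masked to 31 bits), so
enlarging a cohort never reshuffles the images already generated.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .errors import InvalidConfigurationError

#: image height (lines) at which lesion radius ranges are expressed
REFERENCE_HEIGHT = 480

# per-image seed offsets for the two lesion passes (arbitrary fixed primes)
_BRIGHT_SEED_OFFSET = 10_000_019
_RED_SEED_OFFSET = 20_000_003
_SEED_MASK = 0x7FFFFFFF


@dataclass(frozen=True)
class LesionSpec:
    """Appearance model for one lesion family.

    Parameters
    ----------
    kind:
        ``"bright"`` (hard-exudate-like) or ``"red"``
        (microaneurysm/haemorrhage-like).
    count_range:
        Inclusive ``(lo, hi)`` number of lesion instances per image.
    radius_range:
        Lesion radius interval in pixels at :data:`REFERENCE_HEIGHT`.
    contrast_range:
        Peak intensity-offset magnitude relative to the local background,
        in ``(0, 1]``.  The sign is implied by ``kind`` (positive offsets
        for bright lesions, negative for red ones).
    """

    kind: str
    count_range: tuple[int, int]
    radius_range: tuple[float, float]
    contrast_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.kind not in ("bright", "red"):
            raise InvalidConfigurationError(f"unknown lesion kind {self.kind!r}")
        lo, hi = self.count_range
        if not (0 <= lo <= hi):
            raise InvalidConfigurationError(
                f"count_range {self.count_range} must be a non-empty interval >= 0"
            )
        rlo, rhi = self.radius_range
        if not (0 < rlo <= rhi):
            raise InvalidConfigurationError(
                f"radius_range {self.radius_range} must be a non-empty interval > 0"
            )
        clo, chi = self.contrast_range
        if not (0 < clo <= chi <= 1):
            raise InvalidConfigurationError(
                f"contrast_range {self.contrast_range} must lie within (0, 1]"
            )


#: default bright-lesion appearance: mid-sized, fairly high-contrast deposits
DEFAULT_BRIGHT_SPEC = LesionSpec(
    kind="bright",
    count_range=(3, 8),
    radius_range=(4.0, 10.0),
    contrast_range=(0.25, 0.5),
)

#: default red-lesion appearance: smaller and fainter than bright lesions,
#: mirroring the clinical fact that microaneurysms are the subtler sign
DEFAULT_RED_SPEC = LesionSpec(
    kind="red",
    count_range=(3, 10),
    radius_range=(2.5, 7.0),
    contrast_range=(0.18, 0.42),
)


@dataclass
class LesionROI:
    """One lesion instance: its family plus a binary H x W mask."""

    kind: str
    mask: np.ndarray


@dataclass
class LabeledImage:
    """An H x W x 3 raster in [0, 1] with per-lesion ground truth."""

    image: np.ndarray
    label_bright: bool = False
    label_red: bool = False
    rois: list[LesionROI] = field(default_factory=list)
    cohort: str = ""
    id: str = ""
    #: generator geometry (field/disc centres and radii); used internally to
    #: place lesions inside the retinal field and away from the optic disc
    geometry: dict = field(default_factory=dict)

    @property
    def roi_masks(self) -> list[np.ndarray]:
        return [r.mask for r in self.rois]

    def masks_of_kind(self, kind: str) -> list[np.ndarray]:
        return [r.mask for r in self.rois if r.kind == kind]


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one synthetic cohort.

    ``color_shift`` multiplies the three channels after content generation;
    ``jpeg_quality`` (1-100 or ``None``) re-encodes each finished image as
    JPEG in memory so compression artefacts land in the raster itself.
    """

    name: str
    n_normal: int
    n_bright_only: int
    n_red_only: int
    n_both: int
    image_size: tuple[int, int] = (480, 640)
    jpeg_quality: int | None = None
    color_shift: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    bright_spec: LesionSpec = DEFAULT_BRIGHT_SPEC
    red_spec: LesionSpec = DEFAULT_RED_SPEC

    def __post_init__(self) -> None:
        for name in ("n_normal", "n_bright_only", "n_red_only", "n_both"):
            if getattr(self, name) < 0:
                raise InvalidConfigurationError(f"{name} must be >= 0")
        h, w = self.image_size
        if h < 64 or w < 64:
            raise InvalidConfigurationError(
                f"image_size {self.image_size} below the 64x64 minimum"
            )
        if self.jpeg_quality is not None and not (1 <= self.jpeg_quality <= 100):
            raise InvalidConfigurationError("jpeg_quality must be in 1..100 or None")
        if any(g <= 0 for g in self.color_shift):
            raise InvalidConfigurationError("color_shift gains must be > 0")

    @property
    def n_images(self) -> int:
        return self.n_normal + self.n_bright_only + self.n_red_only + self.n_both


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean smooth random field, normalised to unit max amplitude."""
    z = gaussian_filter(rng.standard_normal(shape), sigma)
    amp = np.abs(z).max()
    return z / amp if amp > 0 else z


def generate_background(size: tuple[int, int], seed: int) -> LabeledImage:
    """Generate one lesion-free retina-like image.

    The raster is deterministic in ``(size, seed)``: a circular field of
    reddish-orange tissue with low-frequency shading and fine texture,
    6-9 darker vessel strokes radiating from a brighter optic disc, and a
    near-black surround outside the field.
    """
    h, w = int(size[0]), int(size[1])
    if h < 64 or w < 64:
        raise InvalidConfigurationError(f"image size {size} below the 64x64 minimum")
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = h / 2.0, w / 2.0
    field_radius = 0.46 * min(h, w)
    r = np.hypot(yy - cy, xx - cx)

    # base tissue colour with slow shading and fine granular texture
    base = np.array([0.72, 0.35, 0.13])
    shading = 1.0 + 0.12 * _smooth_noise(rng, (h, w), sigma=h / 7.0)
    texture = 0.015 * _smooth_noise(rng, (h, w), sigma=1.2)
    img = base[None, None, :] * (shading + texture)[:, :, None]

    # optic disc: a bright yellowish-white blob placed off-centre
    side = rng.choice([-1.0, 1.0])
    disc_angle = rng.uniform(-0.35, 0.35)
    disc_cy = cy + 0.55 * field_radius * np.sin(disc_angle)
    disc_cx = cx + side * 0.55 * field_radius * np.cos(disc_angle)
    disc_radius = 0.14 * field_radius
    disc_prof = np.exp(-0.5 * ((yy - disc_cy) ** 2 + (xx - disc_cx) ** 2) / disc_radius**2)
    img += disc_prof[:, :, None] * np.array([0.22, 0.24, 0.12])[None, None, :]

    # vessels: curvilinear random-walk strokes from the disc toward the rim,
    # rendered as a blurred polyline map subtracted mostly from G and B
    n_vessels = int(rng.integers(6, 10))
    stroke = np.zeros((h, w))
    for v in range(n_vessels):
        angle = rng.uniform(0, 2 * np.pi)
        py, px = disc_cy, disc_cx
        step = max(1.2, min(h, w) / 300.0)
        n_steps = int(2.2 * field_radius / step)
        for _ in range(n_steps):
            angle += rng.normal(0.0, 0.09)
            py += step * np.sin(angle)
            px += step * np.cos(angle)
            if np.hypot(py - cy, px - cx) > 0.95 * field_radius:
                break
            iy, ix = int(round(py)), int(round(px))
            if 0 <= iy < h and 0 <= ix < w:
                stroke[iy, ix] = 1.0
    vessel_sigma = max(1.0, h / 420.0)
    vessels = gaussian_filter(stroke, vessel_sigma)
    vmax = vessels.max()
    if vmax > 0:
        vessels /= vmax
    img -= vessels[:, :, None] * np.array([0.18, 0.23, 0.10])[None, None, :]

    # dark surround with a 2 px soft rim
    inside = np.clip((field_radius - r) / 2.0, 0.0, 1.0)
    img = img * inside[:, :, None] + (1.0 - inside)[:, :, None] * 0.02

    img = np.clip(img, 0.0, 1.0)
    return LabeledImage(
        image=img,
        geometry={
            "field_center": (cy, cx),
            "field_radius": field_radius,
            "disc_center": (disc_cy, disc_cx),
            "disc_radius": disc_radius,
        },
    )


def add_lesions(image: LabeledImage, spec: LesionSpec, seed: int) -> LabeledImage:
    """Return a copy of ``image`` with ``n ~ U(count_range)`` lesions added.

    Each lesion is an elliptical Gaussian-profile blob whose peak offset is
    drawn from ``contrast_range`` (sign set by ``spec.kind``) and whose
    radius, drawn from ``radius_range``, is rescaled by
    ``H / REFERENCE_HEIGHT``.  Centres fall inside the retinal field and
    away from the optic disc.  One binary ROI mask (the 2-sigma ellipse
    footprint) is appended per lesion, and the corresponding label is set.
    """
    h, w = image.image.shape[:2]
    rng = np.random.default_rng(seed)
    n = int(rng.integers(spec.count_range[0], spec.count_range[1] + 1))
    if n == 0:
        return image

    geom = image.geometry
    cy, cx = geom.get("field_center", (h / 2.0, w / 2.0))
    field_radius = geom.get("field_radius", 0.46 * min(h, w))
    disc_cy, disc_cx = geom.get("disc_center", (-1e9, -1e9))
    disc_radius = geom.get("disc_radius", 0.0)
    scale = h / REFERENCE_HEIGHT

    if spec.kind == "bright":
        channel_mix = np.array([0.9, 1.0, 0.2])  # yellowish: boost R and G
    else:
        channel_mix = np.array([-0.35, -1.0, -0.75])  # dark red: suppress G, B

    img = image.image.copy()
    rois = list(image.rois)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    for _ in range(n):
        # rejection-sample a centre in the field, clear of the disc
        for _attempt in range(100):
            rad = 0.82 * field_radius * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            ly = cy + rad * np.sin(ang)
            lx = cx + rad * np.cos(ang)
            if np.hypot(ly - disc_cy, lx - disc_cx) > 1.4 * disc_radius:
                break
        radius = rng.uniform(*spec.radius_range) * scale
        contrast = rng.uniform(*spec.contrast_range)
        ratio = rng.uniform(0.7, 1.0)
        theta = rng.uniform(0, np.pi)

        # elliptical squared Mahalanobis distance with sigma = radius / 2
        sa, sb = radius / 2.0, radius * ratio / 2.0
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - lx) * ct + (yy - ly) * st
        v = -(xx - lx) * st + (yy - ly) * ct
        q = (u / sa) ** 2 + (v / sb) ** 2
        profile = np.exp(-0.5 * q)
        img += (contrast * profile)[:, :, None] * channel_mix[None, None, :]
        rois.append(LesionROI(kind=spec.kind, mask=q <= 4.0))  # 2-sigma footprint

    img = np.clip(img, 0.0, 1.0)
    return LabeledImage(
        image=img,
        label_bright=image.label_bright or spec.kind == "bright",
        label_red=image.label_red or spec.kind == "red",
        rois=rois,
        cohort=image.cohort,
        id=image.id,
        geometry=image.geometry,
    )


def _apply_domain_shift(img: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Colour gains, optional JPEG round-trip, then 8-bit quantisation."""
    out = np.clip(img * np.asarray(config.color_shift)[None, None, :], 0.0, 1.0)
    as_u8 = (out * 255.0 + 0.5).astype(np.uint8)
    if config.jpeg_quality is not None:
        buf = _io.BytesIO()
        Image.fromarray(as_u8).save(buf, format="JPEG", quality=config.jpeg_quality)
        buf.seek(0)
        as_u8 = np.asarray(Image.open(buf).convert("RGB"))
    return as_u8.astype(np.float64) / 255.0


def generate_cohort(config: CohortConfig) -> tuple[list[LabeledImage], pd.DataFrame]:
    """Generate a full cohort plus its manifest.

    Images come out in class order (normal, bright-only, red-only, both);
    image ``i`` uses seed ``config.seed + i``, and the lesion passes use
    fixed offsets from that, so the cohort is bit-reproducible and
    extensible.  The manifest carries ``id, cohort, path, label_bright,
    label_red`` with ``path`` set to the filename :func:`write_cohort`
    will use.
    """
    classes = (
        [("normal", False, False)] * config.n_normal
        + [("bright", True, False)] * config.n_bright_only
        + [("red", False, True)] * config.n_red_only
        + [("both", True, True)] * config.n_both
    )
    images: list[LabeledImage] = []
    rows = []
    for i, (cls, want_bright, want_red) in enumerate(classes):
        img_seed = (config.seed + i) & _SEED_MASK
        img = generate_background(config.image_size, img_seed)
        if want_bright:
            img = add_lesions(img, config.bright_spec, (img_seed + _BRIGHT_SEED_OFFSET) & _SEED_MASK)
        if want_red:
            img = add_lesions(img, config.red_spec, (img_seed + _RED_SEED_OFFSET) & _SEED_MASK)
        img.image = _apply_domain_shift(img.image, config)
        img.cohort = config.name
        img.id = f"{config.name}-{i:04d}"
        images.append(img)
        rows.append(
            {
                "id": img.id,
                "cohort": config.name,
                "path": f"images/{img.id}.png",
                "label_bright": img.label_bright,
                "label_red": img.label_red,
            }
        )
    manifest = pd.DataFrame(rows, columns=["id", "cohort", "path", "label_bright", "label_red"])
    return images, manifest


def write_cohort(images: list[LabeledImage], manifest: pd.DataFrame, outdir) -> str:
    """Write a generated cohort to disk.

    Layout: ``images/<id>.png`` (lossless; JPEG degradation, when enabled,
    is already baked into the raster), ``masks/<id>_roiNN_<kind>.png``
    (single-channel 0/255), and ``manifest.csv``.  Returns the manifest
    path.
    """
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    for img in images:
        as_u8 = (np.clip(img.image, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
        Image.fromarray(as_u8).save(outdir / "images" / f"{img.id}.png", format="PNG")
        for j, roi in enumerate(img.rois):
            mask_u8 = roi.mask.astype(np.uint8) * 255
            Image.fromarray(mask_u8, mode="L").save(
                outdir / "masks" / f"{img.id}_roi{j:02d}_{roi.kind}.png", format="PNG"
            )
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return str(manifest_path)


def shifted_config(config: CohortConfig, **overrides) -> CohortConfig:
    """Convenience: derive a domain-shifted sibling cohort config."""
    return replace(config, **overrides)
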