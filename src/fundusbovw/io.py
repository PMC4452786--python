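"""Image, manifest, ROI-mask and run-configuration I/O.

Manifests are CSV files with header ``id,cohort,path,label_bright,
label_red``; ``path`` is resolved relative to the manifest's directory.
Run configurations are flat ``key = value`` text files; every key has a
documented default and unknown keys are rejected.  A short SHA-256 based
hash of the canonical configuration text is recorded in every derived
artifact so mixed-provenance artifacts can be detected.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import FormatError, InvalidConfigurationError, InvalidInputError
from .lowlevel import DetectorConfig
from .synthetic import CohortConfig, LesionROI, LesionSpec

_BOOL_STRINGS = {"0": False, "1": True, "true": True, "false": False}


def read_image(path) -> np.ndarray:
    """Load a PNG/JPEG/TIFF image as an H x W x 3 float array in [0, 1].

    8-bit values map to ``value / 255``.  Grayscale inputs are rejected
    (the pipeline needs colour); an alpha channel, if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    try:
        img = Image.open(path)
        img.load()
    except Exception as exc:  # noqa: BLE001 - re-raise with the path attached
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if img.mode in ("L", "I", "I;16", "1", "P"):
        raise FormatError(f"{path}: expected a 3-channel colour image, got mode {img.mode}")
    if img.mode == "RGBA":
        img = img.convert("RGB")
    if img.mode != "RGB":
        raise FormatError(f"{path}: unsupported image mode {img.mode}")
    return np.asarray(img).astype(np.float64) / 255.0


def write_image(image: np.ndarray, path) -> None:
    """Write an H x W x 3 [0,1] raster as 8-bit PNG (or JPEG by extension)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidInputError(f"expected HxWx3 raster, got shape {image.shape}")
    as_u8 = (np.clip(image, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    Image.fromarray(as_u8).save(path)


def _parse_bool(value, context: str) -> bool:
    s = str(value).strip().lower()
    if s not in _BOOL_STRINGS:
        raise FormatError(f"{context}: cannot parse boolean from {value!r}")
    return _BOOL_STRINGS[s]


def load_manifest(path, check_paths: bool = True, require_labels: bool = True) -> pd.DataFrame:
    """Load and validate a cohort manifest.

    Returns a DataFrame with boolean label columns and an extra
    ``abs_path`` column resolved against the manifest directory.  With
    ``require_labels=False`` (screening-only mode) absent label columns
    are tolerated and filled with ``False``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str)
    required = ["id", "cohort", "path"]
    if require_labels:
        required += ["label_bright", "label_red"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate image ids {sorted(set(dupes))}")
    for col in ("label_bright", "label_red"):
        if col not in df.columns:
            df[col] = False
        else:
            df[col] = [_parse_bool(v, f"{path}:{col}") for v in df[col]]
    base = path.parent
    df["abs_path"] = [str(base / p) for p in df["path"]]
    if check_paths:
        absent = [p for p in df["abs_path"] if not Path(p).exists()]
        if absent:
            raise FormatError(f"{path}: missing image files {absent[:5]}")
    return df


def save_manifest(df: pd.DataFrame, path) -> None:
    out = df[["id", "cohort", "path", "label_bright", "label_red"]].copy()
    for col in ("label_bright", "label_red"):
        out[col] = out[col].astype(bool)
    out.to_csv(path, index=False)


def load_rois(manifest_dir, image_id: str) -> list[LesionROI]:
    """Load the ROI masks written next to a cohort manifest for one image.

    Masks follow the ``masks/<id>_roiNN_<kind>.png`` convention; files are
    returned in name order, which matches generation order.
    """
    mask_dir = Path(manifest_dir) / "masks"
    rois = []
    if mask_dir.exists():
        for p in sorted(mask_dir.glob(f"{image_id}_roi*_*.png")):
            kind = p.stem.rsplit("_", 1)[1]
            mask = np.asarray(Image.open(p)) > 127
            rois.append(LesionROI(kind=kind, mask=mask))
    return rois


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """All tunables of the pipeline, each with its documented default."""

    # detector
    n_scales: int = 5
    sigma0: float = 1.6
    scale_step: float = 1.6
    response_threshold: float = 1e-5
    max_pois: int = 500
    include_color: bool = True
    # codebook
    k: int = 500
    codebook_provenance: str = "kmeans"   # kmeans | random
    per_class_quota: int = 10_000
    kmeans_max_iter: int = 100
    kmeans_tol: float = 1e-4
    # encoding
    normalization: str = "l2"             # none | l1 | l2
    # decision
    svm_c: float = 1.0
    decision_threshold: float = 0.0
    # evaluation
    target_specificity: float = 0.9
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        if self.codebook_provenance not in ("kmeans", "random"):
            raise InvalidConfigurationError(
                f"codebook_provenance must be kmeans|random, got {self.codebook_provenance!r}"
            )
        if self.normalization not in ("none", "l1", "l2"):
            raise InvalidConfigurationError(
                f"normalization must be none|l1|l2, got {self.normalization!r}"
            )
        if self.k < 1:
            raise InvalidConfigurationError("k must be >= 1")
        if not (0.0 <= self.target_specificity <= 1.0):
            raise InvalidConfigurationError("target_specificity must be in [0, 1]")

    def detector_config(self) -> DetectorConfig:
        return DetectorConfig(
            n_scales=self.n_scales,
            sigma0=self.sigma0,
            scale_step=self.scale_step,
            response_threshold=self.response_threshold,
            max_pois=self.max_pois,
            include_color=self.include_color,
        )

    def canonical_text(self) -> str:
        lines = []
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        return "\n".join(lines) + "\n"

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_text().encode()).hexdigest()[:12]

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)


def _coerce(raw: str, target_type):
    if target_type is bool:
        return _parse_bool(raw, "config")
    return target_type(raw)


def load_run_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config file; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"config file not found: {path}")
    known = {f.name: f.type for f in fields(RunConfig)}
    types = {f.name: type(getattr(RunConfig(), f.name)) for f in fields(RunConfig)}
    values = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key not in known:
            raise InvalidConfigurationError(f"{path}:{lineno}: unknown config key {key!r}")
        try:
            values[key] = _coerce(raw.strip("'\""), types[key])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: bad value for {key!r}: {exc}") from exc
    return RunConfig(**values)


def save_run_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        for f in fields(config):
            fh.write(f"{f.name} = {getattr(config, f.name)}\n")


# ---------------------------------------------------------------------------
# cohort (simulation) configuration

_COHORT_KEYS = {
    "name": str,
    "n_normal": int,
    "n_bright_only": int,
    "n_red_only": int,
    "n_both": int,
    "image_height": int,
    "image_width": int,
    "jpeg_quality": str,   # integer or 'none'
    "color_shift": str,    # 'r,g,b' gains
    "seed": int,
    "bright_count_range": str,
    "bright_radius_range": str,
    "bright_contrast_range": str,
    "red_count_range": str,
    "red_radius_range": str,
    "red_contrast_range": str,
}


def _pair(raw: str, cast):
    parts = [p.strip() for p in raw.split(",")]
    if len(parts) != 2:
        raise FormatError(f"expected 'lo,hi', got {raw!r}")
    return (cast(parts[0]), cast(parts[1]))


def load_cohort_config(path) -> CohortConfig:
    """Parse a flat ``key = value`` cohort recipe (one key per field)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cohort config not found: {path}")
    raw: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in _COHORT_KEYS:
            raise InvalidConfigurationError(f"{path}:{lineno}: unknown cohort key {key!r}")
        raw[key] = value
    for req in ("name", "n_normal", "n_bright_only", "n_red_only", "n_both"):
        if req not in raw:
            raise InvalidConfigurationError(f"{path}: missing required key {req!r}")

    from .synthetic import DEFAULT_BRIGHT_SPEC, DEFAULT_RED_SPEC

    def spec_for(kind: str, default: LesionSpec) -> LesionSpec:
        kw = {}
        if f"{kind}_count_range" in raw:
            kw["count_range"] = _pair(raw[f"{kind}_count_range"], int)
        if f"{kind}_radius_range" in raw:
            kw["radius_range"] = _pair(raw[f"{kind}_radius_range"], float)
        if f"{kind}_contrast_range" in raw:
            kw["contrast_range"] = _pair(raw[f"{kind}_contrast_range"], float)
        return replace(default, **kw) if kw else default

    jpeg = raw.get("jpeg_quality", "none").lower()
    color = raw.get("color_shift", "1,1,1").split(",")
    if len(color) != 3:
        raise FormatError(f"{path}: color_shift must be 'r,g,b' gains")
    return CohortConfig(
        name=raw["name"],
        n_normal=int(raw["n_normal"]),
        n_bright_only=int(raw["n_bright_only"]),
        n_red_only=int(raw["n_red_only"]),
        n_both=int(raw["n_both"]),
        image_size=(int(raw.get("image_height", 480)), int(raw.get("image_width", 640))),
        jpeg_quality=None if jpeg == "none" else int(jpeg),
        color_shift=tuple(float(c) for c in color),
        seed=int(raw.get("seed", 0)),
        bright_spec=spec_for("bright", DEFAULT_BRIGHT_SPEC),
        red_spec=spec_for("red", DEFAULT_RED_SPEC),
    )
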