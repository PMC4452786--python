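"""Shared fixtures: a small, strongly-lesioned synthetic cohort pair.

The fixture cohort uses larger/higher-contrast lesions than the package
defaults so that integration checks on few small images stay cleanly
separable and fast; size and domain shift mirror the real use (train
cohort vs. rescaled, colour-shifted, JPEG-compressed test cohort).
"""

import numpy as np
import pytest

from fundusbovw import CohortConfig, LesionSpec, RunConfig, generate_cohort, write_cohort

STRONG_BRIGHT = LesionSpec(
    kind="bright", count_range=(8, 14), radius_range=(12.0, 18.0), contrast_range=(0.5, 0.7)
)
STRONG_RED = LesionSpec(
    kind="red", count_range=(8, 14), radius_range=(7.0, 12.0), contrast_range=(0.45, 0.6)
)


def small_cohort_config(name="fix-a", seed=11, **overrides) -> CohortConfig:
    base = dict(
        name=name,
        n_normal=16,
        n_bright_only=8,
        n_red_only=8,
        n_both=6,
        image_size=(320, 420),
        jpeg_quality=None,
        color_shift=(1.0, 1.0, 1.0),
        seed=seed,
        bright_spec=STRONG_BRIGHT,
        red_spec=STRONG_RED,
    )
    base.update(overrides)
    return CohortConfig(**base)


def small_run_config(seed=5) -> RunConfig:
    # tight PoI cap keeps the pooled lesion mass measurable on small images
    return RunConfig(k=48, per_class_quota=1500, kmeans_max_iter=40, max_pois=120, seed=seed)


@pytest.fixture(scope="session")
def small_cohort():
    """(images, manifest) of the in-memory fixture cohort."""
    return generate_cohort(small_cohort_config())


@pytest.fixture(scope="session")
def cohort_pair_dirs(tmp_path_factory):
    """On-disk train/test cohort directories with domain shift between them."""
    root = tmp_path_factory.mktemp("cohorts")
    cfg_a = small_cohort_config(name="fix-a", seed=11)
    cfg_b = small_cohort_config(
        name="fix-b",
        seed=901,
        n_normal=9,
        n_bright_only=0,
        n_red_only=4,
        n_both=3,
        image_size=(300, 400),
        jpeg_quality=90,
        color_shift=(1.05, 0.97, 0.9),
    )
    dirs = {}
    for cfg in (cfg_a, cfg_b):
        images, manifest = generate_cohort(cfg)
        outdir = root / cfg.name
        write_cohort(images, manifest, outdir)
        dirs[cfg.name] = outdir
    return dirs


@pytest.fixture(scope="session")
def small_descriptor_sets(small_cohort):
    """Whole-image descriptor sets of the fixture cohort (detector defaults)."""
    from fundusbovw import DetectorConfig, detect_pois

    images, _ = small_cohort
    config = DetectorConfig()
    return {img.id: detect_pois(img.image, config, image_id=img.id) for img in images}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
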