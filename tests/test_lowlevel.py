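"""Detector and descriptor contracts, with a brute-force response oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fundusbovw import DescriptorSet, DetectorConfig, detect_pois, restrict_to_rois
from fundusbovw.errors import InvalidInputError
from fundusbovw.lowlevel import save_descriptor_sets, load_descriptor_sets


def blob_image(cy, cx, sigma=6.0, amplitude=0.5, size=(128, 128)):
    yy, xx = np.mgrid[0 : size[0], 0 : size[1]].astype(float)
    blob = amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    return np.clip(np.stack([0.3 + blob] * 3, axis=-1), 0, 1)


class TestDetect:
    def test_constant_image_yields_no_pois(self):
        assert len(detect_pois(np.full((100, 100, 3), 0.5))) == 0

    def test_blob_found_at_response_map_maximum(self):
        """The strongest PoI agrees with a brute-force scan of the DoH map."""
        from scipy.ndimage import gaussian_filter

        img = blob_image(64, 64, sigma=6.0)
        config = DetectorConfig()
        dset = detect_pois(img, config)
        assert len(dset) >= 1
        top = dset.pois[0]
        assert np.hypot(top.x - 64, top.y - 64) <= 6.0

        # independent oracle: global maximum of the scale-normalised
        # determinant-of-Hessian response, via direct filtering
        lum = img @ np.array([0.299, 0.587, 0.114])
        best = (-np.inf, None)
        for s in config.sigmas:
            sm = gaussian_filter(lum, s)
            gy, gx = np.gradient(sm)
            gyy, gyx = np.gradient(gy)
            gxy, gxx = np.gradient(gx)
            resp = s**4 * (gxx * gyy - gxy * gyx)
            idx = np.unravel_index(np.argmax(resp), resp.shape)
            if resp[idx] > best[0]:
                best = (resp[idx], idx)
        oy, ox = best[1]
        assert (top.y, top.x) == (float(oy), float(ox))
        assert top.response == pytest.approx(best[0])

    def test_contract_bounds_and_descriptor_length(self):
        img = blob_image(40, 90, sigma=4.0, size=(120, 150))
        for include_color in (False, True):
            config = DetectorConfig(include_color=include_color)
            dset = detect_pois(img, config)
            for p in dset.pois:
                assert 0 <= p.x < 150 and 0 <= p.y < 120
                assert p.scale > 0
                assert len(p.descriptor) == config.descriptor_dim

    def test_determinism_including_order(self, small_cohort):
        images, _ = small_cohort
        img = images[0].image
        a = detect_pois(img, DetectorConfig())
        b = detect_pois(img, DetectorConfig())
        assert len(a) == len(b)
        for pa, pb in zip(a.pois, b.pois):
            assert (pa.x, pa.y, pa.scale, pa.response) == (pb.x, pb.y, pb.scale, pb.response)
            assert np.array_equal(pa.descriptor, pb.descriptor)

    @pytest.mark.parametrize("dx,dy", [(5, 0), (0, -7), (11, 6)])
    def test_translation_equivariance(self, dx, dy):
        """Shifting the blob shifts its strongest PoI by the same amount (+-1 px)."""
        a = detect_pois(blob_image(64, 64, sigma=5.0))
        b = detect_pois(blob_image(64 + dy, 64 + dx, sigma=5.0))
        assert abs(b.pois[0].x - a.pois[0].x - dx) <= 1
        assert abs(b.pois[0].y - a.pois[0].y - dy) <= 1

    def test_invalid_images_rejected(self):
        with pytest.raises(InvalidInputError):
            detect_pois(np.zeros((50, 50)))
        with pytest.raises(InvalidInputError):
            detect_pois(np.full((50, 50, 3), 2.0))


import functools


@functools.lru_cache(maxsize=1)
def _restrict_dset():
    return detect_pois(blob_image(30, 30, sigma=4.0, size=(100, 100)))


class TestRestrict:
    @pytest.fixture()
    def dset(self):
        return _restrict_dset()

    def test_empty_and_full_masks(self, dset):
        empty = np.zeros((100, 100), bool)
        full = np.ones((100, 100), bool)
        assert len(restrict_to_rois(dset, [empty], "inside")) == 0
        assert len(restrict_to_rois(dset, [], "inside")) == 0
        kept = restrict_to_rois(dset, [full], "inside")
        assert [(p.x, p.y) for p in kept.pois] == [(p.x, p.y) for p in dset.pois]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_partition_property(self, seed):
        """inside + outside always partition the PoI set, for random masks."""
        dset = _restrict_dset()
        rng = np.random.default_rng(seed)
        masks = [rng.random((100, 100)) < rng.uniform(0, 0.5) for _ in range(3)]
        inside = restrict_to_rois(dset, masks, "inside")
        outside = restrict_to_rois(dset, masks, "outside")
        assert len(inside) + len(outside) == len(dset)
        all_pts = sorted((p.x, p.y) for p in inside.pois + outside.pois)
        assert all_pts == sorted((p.x, p.y) for p in dset.pois)

    def test_mismatched_masks_rejected(self, dset):
        with pytest.raises(InvalidInputError):
            restrict_to_rois(dset, [np.ones((100, 100), bool), np.ones((50, 50), bool)], "inside")
        with pytest.raises(InvalidInputError):
            restrict_to_rois(dset, [np.ones((10, 10), bool)], "inside")


def test_descriptor_set_roundtrip(tmp_path, small_descriptor_sets):
    sets = [d for d in small_descriptor_sets.values() if len(d) > 0][:3]
    path = tmp_path / "descr.csv"
    save_descriptor_sets(sets, path, config_hash="abc123")
    loaded, config_hash = load_descriptor_sets(path)
    assert config_hash == "abc123"
    assert [d.image_id for d in loaded] == [d.image_id for d in sets]
    for a, b in zip(sets, loaded):
        assert np.array_equal(a.descriptor_matrix, b.descriptor_matrix)
        assert [p.response for p in a.pois] == [p.response for p in b.pois]
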