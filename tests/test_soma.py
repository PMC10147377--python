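"""Soma quantification: normalization, segmentation, curation, measurement."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from ocquant.errors import ConfigError, ParameterError
from ocquant.image import ChannelImage
from ocquant.soma import (
    CurationCriteria,
    curate_masks,
    local_normalize,
    measure_intensity,
    neuropil_masks,
    neuropil_union,
    segment_somata,
)


# ---------------------------------------------------------------------------
# local normalization
# ---------------------------------------------------------------------------

def _dense_gaussian_kernel(sigma, truncate=4.0):
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _oracle_local_normalize(img, sigma, eps):
    """Brute-force separable convolution with edge padding."""
    k = _dense_gaussian_kernel(sigma)
    r = len(k) // 2

    def smooth(a):
        p = np.pad(a, r, mode="edge")
        tmp = np.apply_along_axis(lambda v: np.convolve(v, k, "valid"), 0, p)
        return np.apply_along_axis(lambda v: np.convolve(v, k, "valid"), 1, tmp)

    centered = img - smooth(img)
    sd = np.sqrt(np.clip(smooth(centered ** 2), 0, None))
    return centered / np.maximum(sd, eps)


class TestLocalNormalize:
    def test_constant_image_maps_to_zero(self):
        out = local_normalize(np.full((32, 32), 7.0), 5, 5)
        assert np.allclose(out, 0.0)
        assert np.isfinite(out).all()

    def test_matches_dense_convolution_oracle_on_checkerboard(self):
        img = np.indices((8, 8)).sum(axis=0) % 2 * 1.0
        got = local_normalize(img, 2, 2, epsilon=1e-9)
        want = _oracle_local_normalize(img, 2.0, 1e-9)
        assert np.allclose(got, want, atol=1e-6)

    def test_affine_invariance(self, rng):
        img = rng.normal(0, 1, (48, 48))
        a, b = 3.5, 12.0
        out1 = local_normalize(img, 4, 4, epsilon=1e-12)
        out2 = local_normalize(a * img + b, 4, 4, epsilon=1e-12)
        assert np.allclose(out1, out2, atol=1e-8)

    def test_rejects_non_2d(self):
        with pytest.raises(ParameterError):
            local_normalize(np.zeros((4, 4, 4)))


# ---------------------------------------------------------------------------
# segmentation fallback
# ---------------------------------------------------------------------------

def _disk_image(centers, radius, shape=(96, 96)):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.zeros(shape)
    for cx, cy in centers:
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2] = 1.0
    return img


class TestSegmentSomata:
    def test_two_disjoint_disks_give_two_labels(self):
        labels = segment_somata(_disk_image([(25, 25), (70, 70)], 8))
        assert labels.max() == 2

    def test_blank_image_gives_empty_mask(self):
        assert segment_somata(np.zeros((64, 64))).max() == 0

    def test_planted_somata_recovered_iou(self, clean_lso):
        params, (image, mask, gt) = clean_lso
        norm = local_normalize(image.channel("soma").astype(float))
        labels = segment_somata(norm)
        matched = 0
        for row in gt.cells.itertuples():
            planted = mask.labels == row.label
            hits = labels[planted]
            hits = hits[hits > 0]
            if hits.size == 0:
                continue
            cand = np.bincount(hits).argmax()
            inter = np.sum(planted & (labels == cand))
            union = np.sum(planted | (labels == cand))
            if inter / union > 0.5:
                matched += 1
        assert matched == len(gt.cells)


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

def _toy_curation_case():
    """One valid disk, one object outside the polygon, one thin sliver."""
    shape = (100, 160)
    labels = np.zeros(shape, np.int32)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    labels[(xx - 50) ** 2 + (yy - 50) ** 2 <= 64] = 1          # valid, inside
    labels[(xx - 140) ** 2 + (yy - 50) ** 2 <= 64] = 2         # outside polygon
    sliver = (np.abs(yy - 20) <= 1) & (np.abs(xx - 50) <= 25)  # ecc ~0.999
    labels[sliver] = 3
    intensity = np.where(labels > 0, 200.0, 10.0)
    image = ChannelImage(np.stack([intensity]), ["ChAT"], (1.0, 1.0))
    polygon = np.array([(5, 5), (100, 5), (100, 95), (5, 95)], float)
    criteria = CurationCriteria(
        lso_polygon=polygon, marker_channels=["ChAT"],
        marker_min_mean={"ChAT": 100.0}, area_range=(50, 2000),
    )
    return labels, image, criteria


class TestCurateMasks:
    def test_toy_case_keeps_only_the_valid_cell(self):
        labels, image, criteria = _toy_curation_case()
        curated, log = curate_masks(labels, image, criteria)
        assert set(np.unique(curated)) == {0, 1}
        log = log.set_index("label")
        assert log.loc[1, "retained"]
        assert "outside_polygon" in log.loc[2, "reasons"]
        assert "too_eccentric" in log.loc[3, "reasons"]

    def test_empty_mask_passes_through(self):
        _, image, criteria = _toy_curation_case()
        curated, log = curate_masks(np.zeros((100, 160), np.int32), image, criteria)
        assert curated.max() == 0 and len(log) == 0

    def test_idempotent(self):
        labels, image, criteria = _toy_curation_case()
        once, _ = curate_masks(labels, image, criteria)
        twice, _ = curate_masks(once, image, criteria)
        assert np.array_equal(once, twice)

    def test_all_valid_unchanged(self):
        labels, image, criteria = _toy_curation_case()
        labels = np.where(labels == 1, 1, 0).astype(np.int32)
        curated, _ = curate_masks(labels, image, criteria)
        assert np.array_equal(curated, labels)

    def test_missing_channel_is_config_error(self):
        labels, image, criteria = _toy_curation_case()
        criteria.marker_channels = ["CGRP"]
        criteria.marker_min_mean = {"CGRP": 1.0}
        with pytest.raises(ConfigError):
            curate_masks(labels, image, criteria)

    def test_decoys_removed_on_synthetic_section(self, decoy_lso):
        params, (image, mask, gt) = decoy_lso
        criteria = CurationCriteria(
            lso_polygon=params.lso_polygon, marker_channels=["soma"],
            marker_min_mean={"soma": 0.4 * params.amplitude},
        )
        curated, log = curate_masks(mask.labels, image, criteria)
        kept = set(np.unique(curated)) - {0}
        genuine = set(gt.cells.loc[gt.cells.decoy == "", "label"])
        decoys = set(gt.cells.loc[gt.cells.decoy != "", "label"])
        assert kept == genuine
        assert kept.isdisjoint(decoys)


# ---------------------------------------------------------------------------
# neuropil annuli
# ---------------------------------------------------------------------------

def _oracle_neuropil(labels, outer, inner):
    """Pixelwise set arithmetic with Euclidean disk dilation."""
    from skimage.morphology import disk, binary_dilation

    inner_union = np.zeros_like(labels, bool)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        inner_union |= binary_dilation(labels == lab, disk(inner))
    out = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        grown = binary_dilation(labels == lab, disk(outer))
        out[int(lab)] = grown & ~inner_union
    return out


class TestNeuropilMasks:
    def test_single_disk_matches_set_arithmetic_oracle(self):
        labels = np.zeros((101, 101), np.int32)
        yy, xx = np.mgrid[0:101, 0:101]
        labels[(xx - 50) ** 2 + (yy - 50) ** 2 <= 100] = 1
        got = neuropil_masks(labels, outer_px=20, inner_px=5)
        want = _oracle_neuropil(labels, 20, 5)
        full = np.zeros((101, 101), bool)
        win, region = got[1]
        full[win] = region
        assert np.array_equal(full, want[1])

    def test_two_cells_match_oracle(self):
        labels = np.zeros((80, 80), np.int32)
        yy, xx = np.mgrid[0:80, 0:80]
        labels[(xx - 30) ** 2 + (yy - 40) ** 2 <= 36] = 1
        labels[(xx - 52) ** 2 + (yy - 40) ** 2 <= 36] = 2
        got = neuropil_masks(labels, outer_px=12, inner_px=4)
        want = _oracle_neuropil(labels, 12, 4)
        for lab in (1, 2):
            full = np.zeros((80, 80), bool)
            win, region = got[lab]
            full[win] = region
            assert np.array_equal(full, want[lab])

    def test_never_touches_inner_dilated_somata(self, clean_lso):
        _, (image, mask, gt) = clean_lso
        regions = neuropil_masks(mask.labels, outer_px=20, inner_px=5)
        dist = ndi.distance_transform_edt(mask.labels == 0)
        inner = dist <= 5
        union = neuropil_union(mask.labels.shape, regions)
        assert not (union & inner).any()

    def test_empty_mask(self):
        assert neuropil_masks(np.zeros((10, 10), np.int32)) == {}

    def test_bad_radii_rejected(self):
        with pytest.raises(ParameterError):
            neuropil_masks(np.zeros((10, 10), np.int32), outer_px=5, inner_px=5)


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

class TestMeasureIntensity:
    def _tiny_case(self, soma_val, bg_val):
        labels = np.zeros((40, 40), np.int32)
        yy, xx = np.mgrid[0:40, 0:40]
        labels[(xx - 20) ** 2 + (yy - 20) ** 2 <= 25] = 1
        img = np.full((40, 40), float(bg_val))
        img[labels == 1] = soma_val
        image = ChannelImage(np.stack([img]), ["pep"], (1.0, 1.0))
        return image, labels

    def test_corrected_is_soma_minus_neuropil(self):
        image, labels = self._tiny_case(100.0, 30.0)
        cells = measure_intensity(image, labels, outer_px=8, inner_px=2)
        row = cells.iloc[0]
        assert row["soma_mean_pep"] == pytest.approx(100.0)
        assert row["neuropil_mean_pep"] == pytest.approx(30.0)
        assert row["corrected_pep"] == pytest.approx(70.0)

    def test_negative_corrected_permitted(self):
        image, labels = self._tiny_case(20.0, 30.0)
        cells = measure_intensity(image, labels, outer_px=8, inner_px=2)
        assert cells.iloc[0]["corrected_pep"] == pytest.approx(-10.0)

    def test_noiseless_synthetic_recovers_planted_values(self, clean_lso):
        params, (image, mask, gt) = clean_lso
        cells = measure_intensity(image, mask)
        merged = cells.merge(gt.cells, on="label")
        got = merged["corrected_peptide"].to_numpy() / params.amplitude
        want = merged["expected_intensity"].to_numpy()
        assert np.allclose(got, want, atol=1e-3)

    def test_empty_neuropil_falls_back_and_flags(self):
        # soma fills almost the whole frame: annulus fully clipped
        labels = np.ones((20, 20), np.int32)
        img = np.full((20, 20), 50.0)
        image = ChannelImage(np.stack([img]), ["pep"], (1.0, 1.0))
        cells = measure_intensity(image, labels, outer_px=8, inner_px=2)
        assert bool(cells.iloc[0]["neuropil_fallback"])
        assert np.isfinite(cells.iloc[0]["corrected_pep"])

    def test_shape_mismatch_rejected(self):
        image, labels = self._tiny_case(1, 0)
        with pytest.raises(ConfigError):
            measure_intensity(image, labels[:20])
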