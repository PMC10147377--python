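"""Cochlear axon analysis: place map, puncta, proximity flags, morphometrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ocquant.axon import (
    AxonSkeleton,
    PlaceFrequencyMap,
    TonotopicAxis,
    classify_calb2,
    classify_npy,
    correlate_metrics,
    detect_puncta,
    mask_channel_by_axon,
    position_to_frequency,
    puncta_frequencies,
    skeleton_metrics,
)
from ocquant.errors import ConfigError, InsufficientDataError, ParameterError
from ocquant.studies import match_puncta, puncta_pipeline

VOX = (0.2, 0.2, 0.2)


# ---------------------------------------------------------------------------
# place–frequency map
# ---------------------------------------------------------------------------

class TestPlaceFrequencyMap:
    def test_endpoints_match_closed_form(self):
        pm = PlaceFrequencyMap()
        assert pm.frequency(0) == pytest.approx(10 ** (156.5 / 82.5), rel=1e-12)
        assert pm.frequency(100) == pytest.approx(10 ** (56.5 / 82.5), rel=1e-12)
        assert pm.frequency(100) == pytest.approx(4.84, abs=0.005)

    def test_round_trip_identity(self):
        pm = PlaceFrequencyMap()
        d = np.linspace(0, 100, 201)
        assert np.max(np.abs(pm.position(pm.frequency(d)) - d)) < 1e-9

    @given(d1=st.floats(0, 100), d2=st.floats(0, 100))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_strictly_decreasing(self, d1, d2):
        pm = PlaceFrequencyMap()
        if d1 < d2:
            assert pm.frequency(d1) > pm.frequency(d2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            position_to_frequency(101.0)


# ---------------------------------------------------------------------------
# masking and detection
# ---------------------------------------------------------------------------

def _sphere(shape, center_vox, radius_vox):
    zz, yy, xx = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    return ((zz - center_vox[0]) ** 2 + (yy - center_vox[1]) ** 2
            + (xx - center_vox[2]) ** 2) <= radius_vox ** 2


class TestMaskChannel:
    def test_empty_mask_zeroes_everything(self):
        chan = np.ones((4, 5, 6))
        assert mask_channel_by_axon(chan, np.zeros((4, 5, 6), bool)).sum() == 0

    def test_full_mask_is_identity(self):
        chan = np.arange(60.0).reshape(3, 4, 5)
        out = mask_channel_by_axon(chan, np.ones((3, 4, 5), bool))
        assert np.array_equal(out, chan)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            mask_channel_by_axon(np.ones((3, 3, 3)), np.ones((3, 3, 4), bool))

    def test_masked_voxel_count_matches_planted(self, clean_cochlea):
        _, (image, axon_mask, gt) = clean_cochlea
        syp = image.channel("syp")
        masked = mask_channel_by_axon(syp, axon_mask)
        bright = syp > 5000
        assert (masked > 5000).sum() == (bright & axon_mask).sum()


class TestDetectPuncta:
    def test_single_small_sphere(self):
        vol = np.zeros((24, 24, 24))
        vol[_sphere(vol.shape, (12, 12, 12), 2)] = 1.0  # d = 0.8 µm
        _, table = detect_puncta(vol, VOX, 0.3)
        assert len(table) == 1

    def test_two_separated_spheres(self):
        vol = np.zeros((24, 24, 60))
        vol[_sphere(vol.shape, (12, 12, 12), 2)] = 1.0
        vol[_sphere(vol.shape, (12, 12, 37), 2)] = 1.0  # 5 µm apart
        _, table = detect_puncta(vol, VOX, 0.3)
        assert len(table) == 2

    def test_oversized_blob_is_split(self):
        # prolate blob, long axis 3.0 µm (15 voxels), width 1.2 µm
        vol = np.zeros((24, 24, 40))
        zz, yy, xx = np.ogrid[0:24, 0:24, 0:40]
        blob = (((xx - 20) / 7.5) ** 2 + ((yy - 12) / 3.0) ** 2
                + ((zz - 12) / 3.0) ** 2) <= 1
        vol[blob] = 1.0
        _, table = detect_puncta(vol, VOX, 0.3)
        assert len(table) >= 2

    def test_blank_volume_gives_empty_table(self):
        labels, table = detect_puncta(np.zeros((8, 8, 8)), VOX, 0.5)
        assert len(table) == 0 and labels.max() == 0

    def test_centroids_in_physical_units(self):
        vol = np.zeros((20, 20, 20))
        vol[_sphere(vol.shape, (10, 10, 10), 2)] = 1.0
        _, table = detect_puncta(vol, (0.5, 0.1, 0.1), 0.3)
        assert table["z_um"].iloc[0] == pytest.approx(5.0, abs=0.3)
        assert table["x_um"].iloc[0] == pytest.approx(1.0, abs=0.06)


class TestProximityClassification:
    def _one_punctum(self):
        vol = np.zeros((16, 16, 32))
        vol[_sphere(vol.shape, (8, 8, 8), 2)] = 1.0
        return detect_puncta(vol, VOX, 0.3)

    def test_punctum_inside_surface_is_positive(self):
        labels, table = self._one_punctum()
        surface = np.zeros(labels.shape, bool)
        surface[_sphere(labels.shape, (8, 8, 8), 4)] = True
        out = classify_npy(labels, table, surface)
        assert bool(out["npy_positive"].iloc[0])

    def test_distant_surface_is_negative(self):
        labels, table = self._one_punctum()
        surface = np.zeros(labels.shape, bool)
        surface[:, :, 14:] = True  # nearest voxel 3+ voxels from the punctum
        out = classify_npy(labels, table, surface)
        assert not bool(out["npy_positive"].iloc[0])

    def test_face_adjacent_counts_as_contact(self):
        labels = np.zeros((5, 5, 7), np.int32)
        labels[2, 2, 2] = 1
        table = pd.DataFrame({"punctum": [1], "x_um": [0.4], "y_um": [0.4],
                              "z_um": [0.4], "n_voxels": [1],
                              "volume_um3": [0.008], "eq_diameter_um": [0.2]})
        surface = np.zeros(labels.shape, bool)
        surface[2, 2, 3] = True  # shares a face, zero gap
        out = classify_calb2(labels, table, surface)
        assert bool(out["on_calb2"].iloc[0])

    def test_partition_is_exhaustive(self, clean_cochlea):
        _, (image, axon_mask, gt) = clean_cochlea
        _, table = puncta_pipeline(image, axon_mask)
        n = len(table)
        quad = (
            (table.npy_positive & table.on_calb2).sum()
            + (table.npy_positive & ~table.on_calb2).sum()
            + (~table.npy_positive & table.on_calb2).sum()
            + (~table.npy_positive & ~table.on_calb2).sum()
        )
        assert quad == n


# ---------------------------------------------------------------------------
# skeleton metrics
# ---------------------------------------------------------------------------

def _chain(points):
    n = len(points)
    return AxonSkeleton(
        nodes=np.arange(1, n + 1),
        parents=np.array([-1] + list(range(1, n))),
        xyz=np.asarray(points, float),
        radius=np.full(n, 0.4),
    )


def _axis():
    return TonotopicAxis((0, 0, 0), (100, 0, 0), 0.0, 100.0)


EMPTY_PUNCTA = pd.DataFrame(columns=["x_um", "y_um", "z_um",
                                     "npy_positive", "on_calb2"])


class TestSkeletonMetrics:
    def test_straight_path(self):
        sk = _chain([(20, 0, 0), (30, 0, 0), (40, 0, 0)])
        m = skeleton_metrics(sk, EMPTY_PUNCTA, _axis())
        pm = PlaceFrequencyMap()
        assert m.n_branch_points == 0
        assert m.branch_depth == 0
        assert m.total_length_um == pytest.approx(20.0)
        assert m.span_khz == pytest.approx(
            abs(pm.frequency(20.0) - pm.frequency(40.0)))
        assert np.isnan(m.pct_npy)

    def test_symmetric_y_tree(self):
        sk = AxonSkeleton(
            nodes=np.array([1, 2, 3, 4]),
            parents=np.array([-1, 1, 2, 2]),
            xyz=np.array([(50, 0, 0), (55, 0, 0), (60, 3, 0), (60, -3, 0.0)]),
            radius=np.full(4, 0.4),
        )
        m = skeleton_metrics(sk, EMPTY_PUNCTA, _axis())
        assert m.n_branch_points == 1
        assert m.branch_depth == 1
        assert m.turn_direction == "apex"

    def test_planted_tree_metrics_match_ground_truth(self, clean_cochlea):
        params, (image, axon_mask, gt) = clean_cochlea
        _, table = puncta_pipeline(image, axon_mask)
        table = puncta_frequencies(table, gt.axis)
        m = skeleton_metrics(gt.skeleton, table, gt.axis)
        assert m.n_branch_points == gt.n_branch_points
        assert m.turn_direction == gt.turn_direction
        pm = PlaceFrequencyMap()
        assert m.stem_freq_khz == pytest.approx(pm.frequency(gt.stem_percent))

    def test_metrics_invariant_to_rigid_translation(self, clean_cochlea):
        params, (image, axon_mask, gt) = clean_cochlea
        _, table = puncta_pipeline(image, axon_mask)
        offset = (12.0, -3.0, 5.0)
        table2 = table.copy()
        table2[["x_um", "y_um", "z_um"]] += offset
        axis2 = TonotopicAxis(
            tuple(np.add(gt.axis.p0, offset)), tuple(np.add(gt.axis.p1, offset)),
            gt.axis.d0_percent, gt.axis.d1_percent)
        m1 = skeleton_metrics(gt.skeleton, table, gt.axis)
        m2 = skeleton_metrics(gt.skeleton.translated(offset), table2, axis2)
        for k, v in m1.to_dict().items():
            if isinstance(v, float) and not np.isnan(v):
                assert m2.to_dict()[k] == pytest.approx(v, rel=1e-9), k
            else:
                assert m2.to_dict()[k] == v or (
                    isinstance(v, float) and np.isnan(v)
                    and np.isnan(m2.to_dict()[k]))


class TestCorrelateMetrics:
    def test_perfect_correlation(self):
        df = pd.DataFrame({"pct_npy": [0, 1, 2, 3.0],
                           "span": [0, 2, 4, 6.0]})
        out = correlate_metrics(df, y_fields=["span"])
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_zero_correlation(self):
        df = pd.DataFrame({"pct_npy": [0, 1, 2.0], "y": [0, 1, 0.0]})
        out = correlate_metrics(df, y_fields=["y"])
        assert out["r"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_definitional_formula(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 12)
            y = rng.normal(0, 1, 12)
            df = pd.DataFrame({"pct_npy": x, "y": y})
            out = correlate_metrics(df, y_fields=["y"])
            xc, yc = x - x.mean(), y - y.mean()
            r_def = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert out["r"].iloc[0] == pytest.approx(r_def, abs=1e-12)

    def test_constant_x_names_field(self):
        df = pd.DataFrame({"pct_npy": [1.0, 1.0, 1.0], "y": [1, 2, 3.0]})
        with pytest.raises(InsufficientDataError, match="pct_npy"):
            correlate_metrics(df, y_fields=["y"])


# ---------------------------------------------------------------------------
# end-to-end flags
# ---------------------------------------------------------------------------

class TestEndToEndClassification:
    def test_noiseless_flags_exact(self, clean_cochlea):
        _, (image, axon_mask, gt) = clean_cochlea
        _, table = puncta_pipeline(image, axon_mask)
        assert len(table) == len(gt.puncta)
        scored = match_puncta(table, gt.puncta)
        assert scored["matched"].all()
        assert (scored["det_npy"] == scored["npy_positive"]).all()
        assert (scored["det_on_calb2"] == scored["on_calb2"]).all()
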