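"""Thresholding, two-pass labeling, morphology, CORSA sifting, mask formation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from wheezescan.segmentation import (
    CorsaRules,
    RegionObject,
    corsa_sift,
    form_wheeze_mask,
    label_components,
    morphological_clean,
    multithreshold_segment,
    row_background,
    threshold_image,
)
from wheezescan.spectrogram import BIN_HZ, COL_SEC, Spectrogram


def flood_fill_partition(mask, connectivity=8):
    """Iterative flood-fill oracle: set of frozensets of pixel coordinates."""
    mask = np.asarray(mask, bool)
    rows, cols = mask.shape
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    seen = np.zeros_like(mask)
    parts = set()
    for r0, c0 in zip(*np.nonzero(mask)):
        if seen[r0, c0]:
            continue
        stack = [(int(r0), int(c0))]
        seen[r0, c0] = True
        comp = []
        while stack:
            r, c = stack.pop()
            comp.append((r, c))
            for dr, dc in neigh:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc] and not seen[rr, cc]:
                    seen[rr, cc] = True
                    stack.append((rr, cc))
        parts.add(frozenset(comp))
    return parts


def as_partition(objects):
    return {frozenset(obj.pixel_set()) for obj in objects}


class TestThresholdImage:
    def test_extremes(self):
        arr = np.arange(12.0).reshape(3, 4)
        assert threshold_image(arr, -1.0).all()
        assert not threshold_image(arr, 12.0).any()

    def test_plus_shaped_toy_example(self):
        arr = np.array([[1, 5, 1], [5, 9, 5], [1, 5, 1]], dtype=float)
        mask = threshold_image(arr, 4.0)
        expected = np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool
        )
        np.testing.assert_array_equal(mask, expected)
        assert mask.sum() == 5


class TestLabelComponents:
    def test_single_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 3] = True
        objs = label_components(mask)
        assert len(objs) == 1 and objs[0].area == 1
        assert objs[0].bbox == (2, 2, 3, 3)

    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(label_components(mask, connectivity=8)) == 1
        assert len(label_components(mask, connectivity=4)) == 2

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_partition_matches_flood_fill_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=(32, 32)) < 0.4
        objs = label_components(mask, connectivity=connectivity)
        assert as_partition(objs) == flood_fill_partition(mask, connectivity)

    def test_partition_matches_scipy_label(self, rng):
        mask = rng.uniform(size=(40, 25)) < 0.35
        labeled, n = ndimage.label(mask, structure=np.ones((3, 3)))
        ours = label_components(mask, connectivity=8)
        assert len(ours) == n
        scipy_parts = {
            frozenset((int(r), int(c)) for r, c in zip(*np.nonzero(labeled == lab)))
            for lab in range(1, n + 1)
        }
        assert as_partition(ours) == scipy_parts

    def test_labels_contiguous_and_raster_ordered(self, rng):
        mask = rng.uniform(size=(20, 20)) < 0.3
        objs = label_components(mask)
        assert [o.label for o in objs] == list(range(1, len(objs) + 1))

    def test_transposition_invariance(self, rng):
        mask = rng.uniform(size=(18, 24)) < 0.35
        direct = as_partition(label_components(mask))
        transposed = {
            frozenset((c, r) for r, c in part)
            for part in as_partition(label_components(mask.T))
        }
        assert direct == transposed


class TestMorphologicalClean:
    def test_identity_for_se1(self, rng):
        mask = rng.uniform(size=(10, 10)) < 0.5
        np.testing.assert_array_equal(morphological_clean(mask, 1), mask)

    def test_isolated_pixel_removed(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        assert not morphological_clean(mask, 3).any()

    def test_solid_bar_survives(self):
        mask = np.zeros((11, 30), bool)
        mask[3:8, 5:25] = True
        np.testing.assert_array_equal(morphological_clean(mask, 3), mask)

    def test_thin_horizontal_ridge_survives(self):
        """A 1-px-thick ridge — the shape of a wheeze — must not be erased."""
        mask = np.zeros((9, 30), bool)
        mask[4, 5:25] = True
        cleaned = morphological_clean(mask, 3)
        assert cleaned[4, 6:24].all()

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            morphological_clean(np.zeros((5, 5), bool), 2)


class TestCorsaSift:
    def _obj(self, rows, cols):
        pixels = [(r, c) for r in rows for c in cols]
        return RegionObject(label=1, pixels=np.array(pixels))

    def test_three_column_object_rejected_as_too_short(self):
        # 3 columns * 29.025 ms = 87.07 ms < 100 ms
        obj = self._obj([20], [10, 11, 12])
        assert obj.duration_ms(COL_SEC) == pytest.approx(87.07, abs=0.01)
        assert corsa_sift([obj], BIN_HZ, COL_SEC) == []

    def test_four_column_object_above_bin6_accepted(self):
        # 4 columns = 116.1 ms; centroid row 18 = 310.1 Hz
        obj = self._obj([18], [10, 11, 12, 13])
        assert obj.duration_ms(COL_SEC) == pytest.approx(116.1, abs=0.05)
        assert obj.centroid_hz(BIN_HZ) == pytest.approx(310.1, abs=0.05)
        assert corsa_sift([obj], BIN_HZ, COL_SEC) == [obj]

    def test_low_frequency_object_rejected(self):
        # centroid row 5 -> 86.1 Hz < 100 Hz regardless of duration
        obj = self._obj([5], list(range(30)))
        assert obj.centroid_hz(BIN_HZ) == pytest.approx(86.13, abs=0.01)
        assert corsa_sift([obj], BIN_HZ, COL_SEC) == []

    def test_sift_is_idempotent_subset(self, rng):
        objs = []
        for i in range(20):
            r = int(rng.integers(1, 120))
            c0 = int(rng.integers(0, 50))
            width = int(rng.integers(1, 15))
            objs.append(self._obj([r], list(range(c0, c0 + width))))
        once = corsa_sift(objs, BIN_HZ, COL_SEC)
        assert set(id(o) for o in once) <= set(id(o) for o in objs)
        assert corsa_sift(once, BIN_HZ, COL_SEC) == once

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        min_dur=st.floats(min_value=50.0, max_value=150.0),
        width=st.integers(min_value=1, max_value=12),
    )
    def test_lowering_duration_rule_never_removes_objects(self, min_dur, width):
        obj = self._obj([30], list(range(width)))
        strict = corsa_sift([obj], BIN_HZ, COL_SEC, CorsaRules(min_duration_ms=min_dur))
        looser = corsa_sift(
            [obj], BIN_HZ, COL_SEC, CorsaRules(min_duration_ms=min_dur / 2)
        )
        assert set(id(o) for o in strict) <= set(id(o) for o in looser)


class TestMultithresholdSegment:
    def _spec(self, arr):
        return Spectrogram(power=arr, bin_hz=BIN_HZ, col_sec=COL_SEC)

    def test_flat_spectrogram_yields_nothing(self):
        arr = np.full((129, 67), -80.0)
        objs = multithreshold_segment(self._spec(arr), np.zeros((129, 67), bool))
        assert objs == []

    def test_single_ridge_recovered_as_one_object(self):
        """400 Hz, ~500 ms ridge 20 dB above a noisy -40 dB background."""
        rng = np.random.default_rng(3)
        arr = -40.0 + 2.0 * rng.standard_normal((129, 67))
        row = int(round(400 / BIN_HZ))
        cols = slice(20, 20 + 17)  # 17 columns ~ 493 ms
        arr[row - 1 : row + 2, cols] = -20.0
        from wheezescan.edges import adaptive_edge_threshold, prewitt_magnitude

        mag = prewitt_magnitude(arr)
        edges = mag > adaptive_edge_threshold(mag, 90.0)
        objs = multithreshold_segment(self._spec(arr), edges)
        assert len(objs) == 1
        obj = objs[0]
        assert obj.centroid_hz(BIN_HZ) == pytest.approx(400, abs=2 * BIN_HZ)
        assert obj.duration_ms(COL_SEC) == pytest.approx(493, abs=2 * COL_SEC * 1000)

    def test_sub_100hz_ridge_is_sifted_out(self):
        rng = np.random.default_rng(4)
        arr = -40.0 + 2.0 * rng.standard_normal((129, 67))
        arr[3:5, 10:40] = -18.0  # ~60 Hz ridge
        row = int(round(400 / BIN_HZ))
        arr[row - 1 : row + 2, 10:40] = -18.0
        from wheezescan.edges import adaptive_edge_threshold, prewitt_magnitude

        mag = prewitt_magnitude(arr)
        edges = mag > adaptive_edge_threshold(mag, 90.0)
        objs = multithreshold_segment(self._spec(arr), edges)
        assert len(objs) == 1
        assert objs[0].centroid_hz(BIN_HZ) > 100

    def test_accepted_objects_satisfy_corsa_by_recomputation(self, synth_study):
        import wheezescan as ws

        frames, labels, _, _, _, pcfg = synth_study
        checked = 0
        for frame, label in zip(frames[:30], labels[:30]):
            res = ws.process_frame(frame, pcfg)
            for obj in res.objects:
                assert obj.duration_ms(COL_SEC) > 100.0
                assert obj.centroid_hz(BIN_HZ) > 100.0
                checked += 1
        assert checked > 0

    def test_row_background_tracks_spectral_shape(self):
        arr = np.tile(np.linspace(-80, -20, 129)[:, None], (1, 67))
        bg = row_background(arr)
        np.testing.assert_allclose(bg[:, 0], arr[:, 0])


class TestFormWheezeMask:
    def test_empty_list_gives_zero_mask(self):
        assert not form_wheeze_mask([], (10, 10)).any()

    def test_popcount_equals_union(self):
        a = RegionObject(1, np.array([(r, c) for r in range(2) for c in range(5)]))
        b = RegionObject(2, np.array([(r, c) for r in range(1, 3) for c in range(3, 8)]))
        mask = form_wheeze_mask([a, b], (10, 10))
        assert mask.sum() == len(a.pixel_set() | b.pixel_set())

    def test_out_of_bounds_rejected(self):
        obj = RegionObject(1, np.array([(11, 2)]))
        with pytest.raises(ValueError):
            form_wheeze_mask([obj], (10, 10))
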