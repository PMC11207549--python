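"""Segmentation, centroid and regional comparison of CAN maps."""

import numpy as np
import pytest

from coactmap import (
    AponeurosisMask,
    CanMap,
    ElectrodeGrid,
    analyze_can_map,
    can_centroid,
    normalize_centroid,
    segment_can_map,
    so_regional_can,
)

G = ElectrodeGrid(n_rows=12, n_cols=5, label="gm_sd")
SO = ElectrodeGrid(n_rows=1, n_cols=7, ied_mm=5.0, label="so_sd")


def cmap(values, grid=G, valid=None, scheme="cs", condition=("GM", "flexed_90", "max_100")):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones_like(values, dtype=bool)
    return CanMap(grid=grid, values=values, valid=valid, scheme=scheme, condition=condition)


def brute_force_components(candidates):
    """Independent 4-connected component enumeration by flood fill."""
    cand = {tuple(p) for p in np.argwhere(candidates)}
    comps = []
    while cand:
        stack = [cand.pop()]
        comp = set(stack)
        while stack:
            r, c = stack.pop()
            for nb in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
                if nb in cand:
                    cand.remove(nb)
                    comp.add(nb)
                    stack.append(nb)
        comps.append(comp)
    return comps


class TestSegmentation:
    def test_single_hot_channel(self):
        v = np.full((12, 5), 0.1)
        v[6, 2] = 1.0
        mask = segment_can_map(cmap(v), AponeurosisMask.full(G))
        assert mask.sum() == 1 and mask[6, 2]

    def test_uniform_map_segments_everything(self):
        mask = segment_can_map(cmap(np.full((12, 5), 0.4)), AponeurosisMask.full(G))
        assert mask.all()

    def test_largest_component_wins(self):
        """Two disjoint supra-threshold blobs (5 vs 3 channels): the larger
        one is returned; cross-checked against a flood-fill enumeration."""
        v = np.zeros((12, 5))
        five = [(1, 1), (1, 2), (2, 1), (2, 2), (3, 1)]
        three = [(9, 3), (10, 3), (10, 4)]
        for p in five:
            v[p] = 1.0
        for p in three:
            v[p] = 1.0
        mask = segment_can_map(cmap(v), AponeurosisMask.full(G))
        comps = brute_force_components(v >= 0.7 * v.max())
        expected = max(comps, key=len)
        assert {tuple(p) for p in np.argwhere(mask)} == expected == set(five)

    def test_tie_broken_by_summed_can(self):
        v = np.zeros((12, 5))
        v[1, 1] = v[2, 1] = 0.8  # size 2, sum 1.6
        v[9, 3] = v[10, 3] = 1.0  # size 2, sum 2.0 -> wins
        mask = segment_can_map(cmap(v), AponeurosisMask.full(G))
        assert {tuple(p) for p in np.argwhere(mask)} == {(9, 3), (10, 3)}

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, size=(12, 5))
        m1 = segment_can_map(cmap(v), AponeurosisMask.full(G))
        m2 = segment_can_map(cmap(137.0 * v), AponeurosisMask.full(G))
        np.testing.assert_array_equal(m1, m2)

    def test_restricted_to_aponeurosis(self):
        v = np.zeros((12, 5))
        v[0, 2] = 5.0  # hottest channel lies outside the mask
        v[6, 2] = 1.0
        apo = AponeurosisMask.from_rows(G, 2, 10)
        mask = segment_can_map(cmap(v), apo)
        assert mask[6, 2] and not mask[0, 2]

    def test_no_valid_channels_rejected(self):
        with pytest.raises(ValueError, match="no valid channel"):
            segment_can_map(
                cmap(np.ones((12, 5)), valid=np.zeros((12, 5), dtype=bool)),
                AponeurosisMask.full(G),
            )

    def test_relative_size_grows_with_blob_sigma(self):
        """A wider planted blob segments more channels at fixed threshold."""
        rows, cols = np.meshgrid(np.arange(12), np.arange(5), indexing="ij")
        sizes = []
        for sigma in (0.8, 1.5, 2.5):
            v = np.exp(-((rows - 6.0) ** 2 + (cols - 2.0) ** 2) / (2 * sigma**2))
            res = analyze_can_map(cmap(v), AponeurosisMask.full(G))
            sizes.append(res.n_segmented)
        assert sizes[0] < sizes[1] < sizes[2]


class TestCentroid:
    def test_single_channel(self):
        v = np.zeros((12, 5))
        v[6, 2] = 1.0
        mask = np.zeros((12, 5), dtype=bool)
        mask[6, 2] = True
        assert can_centroid(cmap(v), mask) == (6.0, 2.0)

    def test_equal_weights_midpoint(self):
        v = np.zeros((12, 5))
        v[2, 1] = v[4, 1] = 0.7
        mask = v > 0
        assert can_centroid(cmap(v), mask) == pytest.approx((3.0, 1.0))

    def test_weighted_mean(self):
        v = np.zeros((12, 5))
        v[2, 1] = 3.0
        v[6, 1] = 1.0
        mask = v > 0
        assert can_centroid(cmap(v), mask) == (3.0, 1.0)

    def test_zero_weights_fall_back_to_unweighted(self, caplog):
        v = np.zeros((12, 5))
        mask = np.zeros((12, 5), dtype=bool)
        mask[2, 0] = mask[4, 2] = True
        with caplog.at_level("INFO"):
            out = can_centroid(cmap(v), mask)
        assert out == (3.0, 1.0)

    def test_centroid_within_mask_bounding_box(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0, 1, size=(12, 5))
        mask = rng.uniform(size=(12, 5)) < 0.4
        mask[0, 0] = True  # ensure nonempty
        r, c = can_centroid(cmap(v), mask)
        rows, cols = np.nonzero(mask)
        assert rows.min() <= r <= rows.max()
        assert cols.min() <= c <= cols.max()


class TestNormalizeCentroid:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ((2.0, 0.0), (0.0, 0.0)),    # at the proximal bound, most medial
            ((10.0, 4.0), (1.0, 1.0)),   # at the distal bound, most lateral
            ((6.0, 2.0), (0.5, 0.5)),    # midway, middle column of 5
        ],
    )
    def test_bounds_and_midpoint(self, raw, expected):
        apo = AponeurosisMask.from_rows(G, 2, 10)
        assert normalize_centroid(raw, apo, G) == pytest.approx(expected)

    def test_degenerate_span_rejected(self):
        apo = AponeurosisMask.from_rows(G, 5, 5)
        with pytest.raises(ValueError, match="degenerate aponeurosis span"):
            normalize_centroid((5.0, 2.0), apo, G)

    def test_clipped_to_unit_square(self):
        apo = AponeurosisMask.from_rows(G, 4, 8)
        pd, ml = normalize_centroid((1.0, 4.0), apo, G)
        assert pd == 0.0 and ml == 1.0


class TestSoRegional:
    def test_identical_arrays_equal_means(self):
        v = np.array([[0.2, 0.3, 0.4, 0.5, 0.4, 0.3, 0.2]])
        med = cmap(v, grid=SO, condition=("SO_medial", "flexed_90", "max_100"))
        lat = cmap(v, grid=SO, condition=("SO_lateral", "flexed_90", "max_100"))
        m, l = so_regional_can(med, lat)
        assert m == pytest.approx(l)

    def test_means_of_valid_channels(self):
        med_v = np.zeros((1, 7))
        med_v[0, :2] = [0.2, 0.4]
        med_valid = np.zeros((1, 7), dtype=bool)
        med_valid[0, :2] = True
        lat_v = np.zeros((1, 7))
        lat_v[0, 0] = 0.3
        lat_valid = np.zeros((1, 7), dtype=bool)
        lat_valid[0, 0] = True
        med = cmap(med_v, grid=SO, valid=med_valid, condition=("SO_medial", "flexed_90", "max_100"))
        lat = cmap(lat_v, grid=SO, valid=lat_valid, condition=("SO_lateral", "flexed_90", "max_100"))
        assert so_regional_can(med, lat) == pytest.approx((0.3, 0.3))

    def test_scheme_mismatch_rejected(self):
        med = cmap(np.ones((1, 7)), grid=SO, scheme="cs",
                   condition=("SO_medial", "flexed_90", "max_100"))
        lat = cmap(np.ones((1, 7)), grid=SO, scheme="ov",
                   condition=("SO_lateral", "flexed_90", "max_100"))
        with pytest.raises(ValueError, match="different schemes"):
            so_regional_can(med, lat)
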