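"""Region-puzzle merging: seeds, weights, candidates, merge loops."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_partition, region_map_from_ids
from epifov.quantize import QuantizedImage, label_regions
from epifov.rpa import (
    BoundingBox,
    NoSeedError,
    RPAConfig,
    ep_anchor,
    merge_ae_region,
    merge_ep_region,
    puzzle_candidate,
    region_weight,
    rpa_merge,
    seed_region,
)
from oracles import rpa_merge_oracle


def mask_to_set(mask):
    return {(int(r), int(c)) for r, c in zip(*np.nonzero(mask))}


def make_map(labels, colors):
    """RegionMap from a palette-index raster and explicit palette colors."""
    palette = np.asarray(colors, np.uint8)
    return label_regions(
        QuantizedImage(labels=np.asarray(labels), palette=palette, q=len(palette))
    )


class TestWeightsAndCandidates:
    def test_literal_weight_formula(self):
        class R:
            centroid = (10.0, 200.0)
            min_row = 180

        assert region_weight(R, 224) == pytest.approx(88.0)

    def test_zero_when_centroid_at_half_edge_row(self):
        class R:
            centroid = (0.0, 112.0)
            min_row = 100

        assert region_weight(R, 224) == pytest.approx(0.0)

    def test_strictly_increasing_in_row(self):
        def r_at(y):
            class R:
                centroid = (0.0, y)
                min_row = int(y)

            return R

        for mode in ("literal", "halved"):
            cfg = RPAConfig(weight_mode=mode)
            w = [region_weight(r_at(y), 100, cfg) for y in (10, 50, 90, 130)]
            assert w == sorted(w) and len(set(w)) == 4

    def test_identical_edges_cancel(self):
        d = {(0, 0), (0, 1)}
        assert puzzle_candidate(d, d, 0.0) == 0.0

    def test_partial_overlap(self):
        assert puzzle_candidate({(0, 0), (0, 1)}, {(0, 1), (0, 2)}, 0.0) == 2.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_set_algebra_identity(self, seed):
        rng = np.random.default_rng(seed)
        d = {(int(r), int(c)) for r, c in rng.integers(0, 6, size=(8, 2))}
        c = {(int(r), int(c_)) for r, c_ in rng.integers(0, 6, size=(8, 2))}
        w = float(rng.normal())
        expected = len(d) + len(c) - 2 * len(d & c) - w
        assert puzzle_candidate(d, c, w) == pytest.approx(expected)


class TestSeedRegion:
    def test_window_covering_single_region(self):
        rm = make_map(np.zeros((6, 6), int), [[90, 90, 90]])
        assert seed_region(rm, (3, 3), 4, "brightest") == 1

    def test_darkest_polarity(self):
        labels = np.zeros((6, 6), int)
        labels[:, 3:] = 1
        rm = make_map(labels, [[250, 250, 250], [20, 20, 20]])
        rid = seed_region(rm, (3, 3), 6, "darkest")
        assert rm.regions[rid].color == (20, 20, 20)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(17)
        ids = random_partition(rng, (12, 12), 5)
        rm = region_map_from_ids(ids)
        rid = seed_region(rm, (6, 6), 6, "brightest")
        # exhaustive: scan window pixels, collect regions, pick by the rule
        rows = slice(6 - 3, 6 + 3)
        cols = slice(6 - 3, 6 + 3)
        cands = {int(v) for v in np.unique(rm.region_labels[rows, cols])}
        best = max(
            (rm.regions[c] for c in cands),
            key=lambda r: (sum(r.color), r.area, -r.id),
        )
        assert rid == best.id

    def test_no_region_pixels_raises(self):
        rm = make_map(np.zeros((6, 6), int), [[90, 90, 90]])
        with pytest.raises(NoSeedError):
            seed_region(rm, (3, 3), 6, "brightest", admissible=lambda r: False)


class TestRpaMerge:
    def test_seed_only_when_no_admissible_neighbors(self):
        labels = np.zeros((8, 8), int)
        labels[2:5, 2:5] = 1
        labels[3, 3] = 2  # hole-ish inner pixel of another color
        rm = make_map(labels, [[10, 10, 10], [200, 200, 200], [90, 90, 90]])
        seed = int(rm.region_labels[2, 2])
        res = rpa_merge(rm, seed, admissible=lambda r: False, weight_fn=lambda r: 0)
        # fill_holes absorbs the enclosed pixel even though nothing merges
        assert mask_to_set(res.mask) == {(r, c) for r in range(2, 5) for c in range(2, 5)}
        assert res.merged_ids == [seed]

    def test_two_adjacent_squares_merge_to_rectangle(self):
        # 4x8 raster split into two 4x4 squares: the left square is
        # completely surrounded by the right one inside the raster, and the
        # merged outline (20 px) beats the sum of standalone edges
        labels = np.zeros((4, 8), int)
        labels[:, 4:] = 1
        rm = make_map(labels, [[50, 50, 50], [150, 150, 150]])
        seed = int(rm.region_labels[0, 0])
        res = rpa_merge(rm, seed, admissible=lambda r: True, weight_fn=lambda r: 0)
        assert res.mask.all()
        assert res.mask.sum() == 32

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ids = random_partition(rng, (16, 16), 6)
        rm = region_map_from_ids(ids)
        rids = sorted(rm.regions)
        weights = {rid: float(rng.uniform(-4, 12)) for rid in rids}
        seed_rid = int(rng.choice(rids))
        # occasionally knock out some regions as inadmissible
        admissible_ids = {
            rid for rid in rids if rid == seed_rid or rng.random() < 0.8
        }
        res = rpa_merge(
            rm,
            seed_rid,
            admissible=lambda r: r.id in admissible_ids,
            weight_fn=lambda r: weights[r.id],
        )
        expected = rpa_merge_oracle(
            rm.region_labels.tolist(), seed_rid, admissible_ids, weights
        )
        assert mask_to_set(res.mask) == expected

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_trace_invariants(self, seed):
        rng = np.random.default_rng(seed)
        ids = random_partition(rng, (16, 16), 6)
        rm = region_map_from_ids(ids)
        rids = sorted(rm.regions)
        weights = {rid: float(rng.uniform(0, 10)) for rid in rids}
        seed_rid = int(rng.choice(rids))
        res = rpa_merge(
            rm, seed_rid, lambda r: True, lambda r: weights[r.id]
        )
        # committed sweep puzzle values strictly decrease
        assert all(a > b for a, b in zip(res.committed_p, res.committed_p[1:]))
        # termination bound: iterations never exceed the region count
        assert res.iterations <= len(rm.regions) + 1
        # merged ids are unique and include the seed
        assert res.merged_ids[0] == seed_rid
        assert len(set(res.merged_ids)) == len(res.merged_ids)


class TestEpMerging:
    def _nested_map(self):
        # seed bright core, ring R1 inside the box, outer R2 exceeding it
        labels = np.zeros((20, 20), int)  # background region 0
        labels[4:16, 4:16] = 1  # R2: large mid ring, exceeds the box
        labels[6:14, 6:14] = 2  # R1: inside box
        labels[8:12, 8:12] = 3  # bright core
        return make_map(
            labels,
            [[60, 60, 60], [100, 100, 100], [150, 150, 150], [240, 240, 240]],
        )

    def test_merges_contained_neighbor_but_not_overflowing_one(self):
        rm = self._nested_map()
        box = BoundingBox(x=5, y=5, width=10, height=10)
        ep = merge_ep_region(rm, box, u=4)
        # core ∪ R1 merged; R2 exceeds the box and stays out
        assert mask_to_set(ep.mask) == {
            (r, c) for r in range(6, 14) for c in range(6, 14)
        }
        assert not ep.seed_overflowed_box

    def test_overflowing_seed_returned_unmerged(self):
        labels = np.zeros((20, 20), int)
        labels[2:18, 2:18] = 1  # bright region larger than the box
        rm = make_map(labels, [[40, 40, 40], [230, 230, 230]])
        box = BoundingBox(x=6, y=6, width=6, height=6)
        ep = merge_ep_region(rm, box, u=4)
        assert ep.seed_overflowed_box
        assert mask_to_set(ep.mask) == {
            (r, c) for r in range(2, 18) for c in range(2, 18)
        }

    def test_box_inside_one_huge_region(self):
        rm = make_map(np.zeros((16, 16), int), [[200, 200, 200]])
        box = BoundingBox(x=4, y=4, width=6, height=6)
        ep = merge_ep_region(rm, box, u=4)
        assert ep.seed_overflowed_box
        assert ep.mask.all()

    def test_ep_mask_stays_inside_box_unless_overflow(self):
        rm = self._nested_map()
        box = BoundingBox(x=5, y=5, width=10, height=10)
        ep = merge_ep_region(rm, box, u=4)
        rows, cols = np.nonzero(ep.mask)
        assert rows.min() >= box.y and rows.max() < box.y + box.height
        assert cols.min() >= box.x and cols.max() < box.x + box.width


class TestEpAnchor:
    def test_reference_geometry(self):
        # EP mask whose column-418 pixels span rows 224..371: the anchor
        # window center lands at (418, 112)
        mask = np.zeros((480, 640), bool)
        mask[224:372, 300:419] = True
        a = ep_anchor(mask)
        assert (a.x_rho, a.y_rho, a.y_e) == (300, 371, 224)
        # force the bottom-most pixel into column 418
        mask2 = np.zeros((480, 640), bool)
        mask2[224:371, 300:500] = True
        mask2[371, 418] = True
        a2 = ep_anchor(mask2)
        assert (a2.x_rho, a2.y_rho, a2.y_e) == (418, 371, 224)
        assert (a2.x_rho, a2.y_e // 2) == (418, 112)

    def test_single_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[3, 2] = True
        a = ep_anchor(mask)
        assert (a.x_rho, a.y_rho, a.y_e) == (2, 3, 3)

    def test_solid_rectangle(self):
        mask = np.zeros((10, 10), bool)
        mask[2:7, 3:8] = True
        a = ep_anchor(mask)
        assert a.y_e == 2 and a.y_rho == 6 and a.x_rho == 3  # leftmost bottom

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            ep_anchor(np.zeros((4, 4), bool))

    def test_y_e_never_below_rho(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            mask = np.zeros((12, 12), bool)
            r0, c0 = rng.integers(0, 8, size=2)
            mask[r0 : r0 + rng.integers(1, 4), c0 : c0 + rng.integers(1, 4)] = True
            a = ep_anchor(mask)
            assert a.y_e <= a.y_rho


class TestAeMerging:
    def _scene(self):
        """40x40 scene shaped like the common airway topology: a bright EP
        block at the bottom, a U-shaped dark airway seed whose cavity is
        tiled by two mid-tone pieces (candidates that smooth the outline
        and pass), and a piece above the airway that fails."""
        labels = np.zeros((40, 40), int)
        labels[28:38, 8:33] = 1  # EP block, rows 28..37 → Y_e = 28
        labels[10:28, 10:26] = 2  # airway U: rect minus the cavity below
        labels[16:22, 14:22] = 3  # R1: lower cavity half (w > 0, passes)
        labels[10:16, 14:22] = 4  # R2: upper cavity half (passes)
        labels[4:10, 12:24] = 5  # R3: sits on top, fails
        return make_map(
            labels,
            [
                [120, 120, 120],
                [230, 230, 230],
                [15, 15, 15],
                [70, 70, 70],
                [80, 80, 80],
                [90, 90, 90],
            ],
        )

    def test_no_dark_region_above_edge_means_complete_obstruction(self):
        labels = np.zeros((30, 30), int)
        labels[20:28, 5:25] = 1
        rm = make_map(labels, [[120, 120, 120], [230, 230, 230]])
        ep = np.zeros((30, 30), bool)
        ep[20:28, 5:25] = True
        ae = merge_ae_region(rm, ep_anchor(ep), h=6)
        # background spans the whole raster → inadmissible; no seed
        assert ae.area == 0

    def test_merges_passing_neighbors_only(self):
        rm = self._scene()
        ep = np.zeros((40, 40), bool)
        ep[28:38, 8:33] = True
        anchor = ep_anchor(ep)
        assert anchor.y_e == 28
        ae = merge_ae_region(rm, anchor, h=14)
        got = mask_to_set(ae.mask)
        # cavity pieces merged: final airway is the full filled rectangle
        assert got == {(r, c) for r in range(10, 28) for c in range(10, 26)}
        # nothing below the epiglottis top edge
        rows, _ = np.nonzero(ae.mask)
        assert rows.max() <= anchor.y_e

    def test_ae_never_crosses_epiglottis_top_edge(self):
        rm = self._scene()
        ep = np.zeros((40, 40), bool)
        ep[28:38, 8:33] = True
        anchor = ep_anchor(ep)
        for h in (6, 10, 14):
            ae = merge_ae_region(rm, anchor, h=h)
            if ae.area:
                rows, _ = np.nonzero(ae.mask)
                assert rows.max() <= anchor.y_e

    def test_phantom_blob_area_recovered(self, clean_phantom):
        from epifov.detector import mock_detect, select_box
        from epifov.pipeline import analyze_frame

        config, frames, gt = clean_phantom
        n = 5  # a breathing frame outside slip/occlusion
        truth = gt.frames[n - 1]
        box = select_box(mock_detect(gt)[n])
        r = analyze_frame(frames[n - 1], box, n=n, keep_masks=True)
        assert r.status == "ok"
        assert abs(r.omega - truth.area) / truth.area <= 0.05
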