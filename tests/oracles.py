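"""Independent brute-force oracles used to validate the package.

Everything here is implemented with plain Python data structures (lists,
sets, dicts) and no calls into the package's own numerics, so agreement
between the two routes is meaningful.
"""

from __future__ import annotations

from collections import deque


# ---------------------------------------------------------------------------
# median cut on a raw pixel list
# ---------------------------------------------------------------------------

def median_cut_oracle(pixels, q):
    """Return (palette, assignment) for a list of (r, g, b) tuples.

    Same conventions as the package states: split the box with the largest
    single-channel range (ties: larger pixel count, then lower position) at
    its pixel-count median along that channel; representative = mean color
    rounded half up; pixels map to their own box.
    """
    # unique colors in lexicographic order with counts
    counts = {}
    for p in pixels:
        counts[tuple(int(v) for v in p)] = counts.get(tuple(int(v) for v in p), 0) + 1
    colors = sorted(counts)
    boxes = [list(colors)]
    while len(boxes) < q:
        best = None
        best_pos = best_chan = -1
        for pos, box in enumerate(boxes):
            ranges = [
                max(c[ch] for c in box) - min(c[ch] for c in box) for ch in range(3)
            ]
            chan = ranges.index(max(ranges))
            r = ranges[chan]
            if r == 0:
                continue
            key = (r, sum(counts[c] for c in box), -pos)
            if best is None or key > best:
                best, best_pos, best_chan = key, pos, chan
        if best is None:
            break
        box = sorted(boxes[best_pos], key=lambda c: c[best_chan])
        total = sum(counts[c] for c in box)
        cum = 0
        split = len(box) - 2
        for i, c in enumerate(box):
            cum += counts[c]
            if cum >= total / 2.0:
                split = min(i, len(box) - 2)
                break
        boxes[best_pos] = box[: split + 1]
        boxes.append(box[split + 1 :])

    palette = []
    color_to_box = {}
    for b, box in enumerate(boxes):
        total = sum(counts[c] for c in box)
        mean = [
            sum(c[ch] * counts[c] for c in box) / total for ch in range(3)
        ]
        palette.append(tuple(int(m + 0.5) for m in mean))
        for c in box:
            color_to_box[c] = b
    assignment = [color_to_box[tuple(int(v) for v in p)] for p in pixels]
    return palette, assignment


# ---------------------------------------------------------------------------
# binary mask primitives by exhaustive scanning
# ---------------------------------------------------------------------------

def _in_bounds(r, c, h, w):
    return 0 <= r < h and 0 <= c < w


def flood_regions_oracle(raster, connectivity=8):
    """Connected components of equal value; returns list of pixel sets."""
    h, w = len(raster), len(raster[0])
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = [[False] * w for _ in range(h)]
    regions = []
    for r0 in range(h):
        for c0 in range(w):
            if seen[r0][c0]:
                continue
            val = raster[r0][c0]
            comp = set()
            queue = deque([(r0, c0)])
            seen[r0][c0] = True
            while queue:
                r, c = queue.popleft()
                comp.add((r, c))
                for dr, dc in nbrs:
                    rr, cc = r + dr, c + dc
                    if (
                        _in_bounds(rr, cc, h, w)
                        and not seen[rr][cc]
                        and raster[rr][cc] == val
                    ):
                        seen[rr][cc] = True
                        queue.append((rr, cc))
            regions.append(comp)
    return regions


def fill_holes_oracle(mask_set, shape):
    """Flood the 4-connected background from the border; unreached
    background pixels are holes and get filled."""
    h, w = shape
    outside = set()
    queue = deque(
        (r, c)
        for r in range(h)
        for c in range(w)
        if (r in (0, h - 1) or c in (0, w - 1)) and (r, c) not in mask_set
    )
    outside.update(queue)
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if (
                _in_bounds(rr, cc, h, w)
                and (rr, cc) not in mask_set
                and (rr, cc) not in outside
            ):
                outside.add((rr, cc))
                queue.append((rr, cc))
    return {(r, c) for r in range(h) for c in range(w) if (r, c) not in outside}


def edge_oracle(mask_set, shape):
    """Set pixels with >= 1 four-neighbor outside (border counts outside)."""
    h, w = shape
    edge = set()
    for r, c in mask_set:
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if not _in_bounds(rr, cc, h, w) or (rr, cc) not in mask_set:
                edge.add((r, c))
                break
    return edge


# ---------------------------------------------------------------------------
# greedy region-puzzle merge by exhaustive re-evaluation
# ---------------------------------------------------------------------------

def rpa_merge_oracle(id_raster, seed_id, admissible_ids, weights):
    """Re-implementation of the committed puzzle-merge loop on sets.

    id_raster: 2D list of region ids; admissible_ids: set; weights: dict
    id -> w_j.  Returns the final mask as a set of (row, col).
    """
    h, w = len(id_raster), len(id_raster[0])
    cells = {}
    for r in range(h):
        for c in range(w):
            cells.setdefault(id_raster[r][c], set()).add((r, c))

    def ring_ids(t):
        ids = set()
        for r, c in t:
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if _in_bounds(rr, cc, h, w) and (rr, cc) not in t:
                    ids.add(id_raster[rr][cc])
        return ids

    merged = {seed_id}
    t = fill_holes_oracle(cells[seed_id], (h, w))
    while True:
        ids = ring_ids(t) - merged
        if len(ids) == 1:
            (j,) = ids
            if j in admissible_ids:
                t = fill_holes_oracle(t | cells[j], (h, w))
                merged.add(j)
                ids = ring_ids(t) - merged
        p_k = len(edge_oracle(t, (h, w)))
        passing = []
        for j in sorted(ids):
            if j not in admissible_ids:
                continue
            union_edge = len(edge_oracle(t | cells[j], (h, w)))
            if union_edge - weights.get(j, 0.0) <= p_k:
                passing.append(j)
        if not passing:
            break
        t_new = set(t)
        for j in passing:
            t_new |= cells[j]
        t_new = fill_holes_oracle(t_new, (h, w))
        if len(edge_oracle(t_new, (h, w))) >= p_k:
            break
        t = t_new
        merged.update(passing)
    return t
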