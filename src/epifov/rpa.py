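"""Region puzzle algorithm (RPA): seeded region merging by edge smoothness.

The RPA treats quantized color regions as jigsaw pieces.  Starting from a
seed region (the "puzzle board"), it repeatedly considers admissible
neighboring regions and accepts a merge when the merged outline is no
rougher than the current one: with C_k the boundary-edge set of the current
target T_k and P_k = |C_k| its puzzle value, a neighbor R_j is a passing
candidate when

    P_j^{k+1} = |edge(R_j ∪ T_k)| − w_j  <=  P_k

where w_j is a positional weight (zero while merging the epiglottis, and
w_j = ȳ_j − Y_e/2 while merging the airway field of view, so pieces closer
to the epiglottis merge more readily).  All passing candidates of a round
are merged in one sweep, holes are filled, and the sweep is committed only
if the puzzle value strictly decreased; otherwise the algorithm stops.  A
target completely surrounded by a single admissible region absorbs it
directly.

Two instantiations are provided:

* :func:`merge_ep_region` — grows the epiglottis (EP) region from the
  brightest region at the detector bounding-box center, restricted to
  regions fully inside the box.
* :func:`merge_ae_region` — grows the airway field of view (AE region)
  from the darkest region in a window above the epiglottis top edge,
  restricted to regions lying entirely above that edge.  An empty result
  means the airway is completely obstructed in this frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal

import numpy as np
from scipy import ndimage

from .quantize import RegionInfo, RegionMap, boundary_edge, fill_holes

__all__ = [
    "BoundingBox",
    "EPAnchor",
    "EPRegion",
    "AERegion",
    "MergeResult",
    "RPAConfig",
    "NoSeedError",
    "NoEpiglottisRegionError",
    "region_weight",
    "puzzle_candidate",
    "seed_region",
    "rpa_merge",
    "merge_ep_region",
    "ep_anchor",
    "merge_ae_region",
]

_CROSS = ndimage.generate_binary_structure(2, 1)


class NoSeedError(RuntimeError):
    """The seed window contains no admissible region pixels."""


class NoEpiglottisRegionError(NoSeedError):
    """No epiglottis region could be seeded inside the bounding box."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned detector box: top-left (x, y), size (width, height)."""

    x: int
    y: int
    width: int
    height: int
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("bounding box must have positive width and height")

    @property
    def center(self) -> tuple[int, int]:
        return (self.x + self.width // 2, self.y + self.height // 2)

    @property
    def area(self) -> int:
        return self.width * self.height

    def contains_region(self, r: RegionInfo) -> bool:
        return (
            r.min_col >= self.x
            and r.max_col < self.x + self.width
            and r.min_row >= self.y
            and r.max_row < self.y + self.height
        )


@dataclass(frozen=True)
class EPAnchor:
    """Reference geometry of the EP region.

    ``(x_rho, y_rho)`` is the lowest-on-screen EP pixel (maximum row, ties
    to the smallest column); ``y_e`` is the row of the EP edge point in the
    same column with the minimum row (the epiglottis top edge).  The AE
    seed window is centered at ``(x_rho, y_e // 2)``.
    """

    x_rho: int
    y_rho: int
    y_e: int


@dataclass
class EPRegion:
    mask: np.ndarray
    anchor: EPAnchor
    seed_overflowed_box: bool = False

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class AERegion:
    mask: np.ndarray
    trace: "MergeResult | None" = None

    @property
    def area(self) -> int:
        """Airway field-of-view measurement ω = |A| in pixels."""
        return int(self.mask.sum())


@dataclass
class MergeResult:
    """Final mask plus the committed-iteration trace of one RPA run."""

    mask: np.ndarray
    merged_ids: list[int]
    committed_p: list[int] = field(default_factory=list)
    accepted_per_iteration: list[list[int]] = field(default_factory=list)
    iterations: int = 0


@dataclass(frozen=True)
class RPAConfig:
    """Tunable interpretation switches of the merge machinery.

    weight_mode
        ``"literal"`` reads the airway weight as ȳ_j − Y_e/2 (the printed
        formula); ``"halved"`` as (ȳ_j − Y_e)/2.  Both are strictly
        increasing in ȳ_j and produce the same candidate ordering shape.
    region_y
        Which row statistic stands in for ȳ_j: the region centroid row
        (default) or its topmost row.
    """

    weight_mode: Literal["literal", "halved"] = "literal"
    region_y: Literal["centroid", "top"] = "centroid"


def region_weight(
    region: RegionInfo, y_e: float, config: RPAConfig = RPAConfig()
) -> float:
    """Positional weight w_j of a region for AE merging.

    Strictly increasing in the region's row coordinate: regions nearer the
    epiglottis (larger row) are easier to merge.
    """
    y_j = region.centroid[1] if config.region_y == "centroid" else region.min_row
    if config.weight_mode == "literal":
        return float(y_j - y_e / 2.0)
    return float((y_j - y_e) / 2.0)


def puzzle_candidate(
    d_j: Iterable[tuple[int, int]], c_k: Iterable[tuple[int, int]], w_j: float
) -> float:
    """Candidate puzzle value |D_j ⊕ C_k| − w_j on pixel-coordinate sets."""
    d, c = set(d_j), set(c_k)
    return float(len(d ^ c)) - w_j


# ---------------------------------------------------------------------------
# seed selection
# ---------------------------------------------------------------------------

def _window_slices(
    shape: tuple[int, int], center: tuple[int, int], size: int
) -> tuple[slice, slice]:
    cx, cy = center
    half = size // 2
    r0 = max(0, cy - half)
    r1 = min(shape[0], cy - half + size)
    c0 = max(0, cx - half)
    c1 = min(shape[1], cx - half + size)
    return slice(r0, r1), slice(c0, c1)


def seed_region(
    region_map: RegionMap,
    center: tuple[int, int],
    window: int,
    polarity: Literal["brightest", "darkest"],
    admissible: Callable[[RegionInfo], bool] | None = None,
) -> int:
    """Pick the brightest/darkest region intersecting an s×s window.

    Brightness is the sum R+G+B of the region's palette color; ties go to
    the larger area, then the lower region id.  The window is clipped at
    raster borders.  Raises :class:`NoSeedError` when no (admissible)
    region pixel falls inside the window.
    """
    rs, cs = _window_slices(region_map.shape, center, window)
    ids = np.unique(region_map.region_labels[rs, cs])
    best_key = None
    best_id = None
    for rid in ids:
        info = region_map.regions[int(rid)]
        if admissible is not None and not admissible(info):
            continue
        s = sum(info.color)
        bright = s if polarity == "brightest" else -s
        key = (bright, info.area, -info.id)
        if best_key is None or key > best_key:
            best_key, best_id = key, info.id
    if best_id is None:
        raise NoSeedError(f"no admissible region pixels in window at {center}")
    return best_id


# ---------------------------------------------------------------------------
# merge loop
# ---------------------------------------------------------------------------

def _edge_count(mask: np.ndarray) -> int:
    return int(boundary_edge(mask).sum())


def _neighbor_ids(
    region_map: RegionMap, mask: np.ndarray, merged: set[int]
) -> list[int]:
    ring = ndimage.binary_dilation(mask, structure=_CROSS) & ~mask
    ids = np.unique(region_map.region_labels[ring])
    return [int(i) for i in ids if int(i) not in merged]


def _shared_border(region_map: RegionMap, mask: np.ndarray, rid: int) -> int:
    ring = ndimage.binary_dilation(mask, structure=_CROSS) & ~mask
    return int((region_map.region_labels[ring] == rid).sum())


def rpa_merge(
    region_map: RegionMap,
    seed: int,
    admissible: Callable[[RegionInfo], bool],
    weight_fn: Callable[[RegionInfo], float],
) -> MergeResult:
    """Run the committed puzzle-merge loop from a seed region.

    Per iteration: absorb a single fully-surrounding admissible region
    directly; evaluate every admissible 4-neighbor R_j with
    P_j = |edge(R_j ∪ T)| − w_j and merge all candidates with P_j <= P in
    one sweep (descending shared-border length, ties by id); fill holes;
    commit only if the puzzle value strictly decreased.  Stops when no
    candidate passes or the value fails to decrease.  A seed-only result
    is valid.
    """
    L = region_map.region_labels
    merged: set[int] = {seed}
    t = fill_holes(L == seed)
    result = MergeResult(mask=t, merged_ids=[seed])
    max_iter = len(region_map.regions) + 1

    for _ in range(max_iter):
        result.iterations += 1
        # direct merge: target completely surrounded by one admissible region
        neighbors = _neighbor_ids(region_map, t, merged)
        if len(neighbors) == 1:
            info = region_map.regions[neighbors[0]]
            if admissible(info):
                t = fill_holes(t | (L == info.id))
                merged.add(info.id)
                result.merged_ids.append(info.id)
                result.accepted_per_iteration.append([info.id])
                neighbors = _neighbor_ids(region_map, t, merged)

        p_k = _edge_count(t)
        candidates = [
            region_map.regions[rid]
            for rid in neighbors
            if admissible(region_map.regions[rid])
        ]
        passing: list[RegionInfo] = []
        for info in candidates:
            union_edge = _edge_count(t | (L == info.id))
            if union_edge - weight_fn(info) <= p_k:
                passing.append(info)
        if not passing:
            break
        passing.sort(
            key=lambda r: (-_shared_border(region_map, t, r.id), r.id)
        )
        t_new = t.copy()
        for info in passing:
            t_new |= L == info.id
        t_new = fill_holes(t_new)
        p_new = _edge_count(t_new)
        if p_new >= p_k:
            break  # sweep not committed
        t = t_new
        for info in passing:
            merged.add(info.id)
            result.merged_ids.append(info.id)
        result.accepted_per_iteration.append([r.id for r in passing])
        result.committed_p.append(p_new)

    result.mask = t
    return result


# ---------------------------------------------------------------------------
# EP / AE instantiations
# ---------------------------------------------------------------------------

def merge_ep_region(
    region_map: RegionMap,
    box: BoundingBox,
    u: int | None = None,
    config: RPAConfig = RPAConfig(),
) -> EPRegion:
    """Merge the epiglottis region inside a detector bounding box.

    Seeds with the brightest region in a u×u window at the box center
    (default u = round(H_B/2), at least 8).  Only regions fully inside the
    box may merge (zero weight).  If the seed region itself spills outside
    the box it is returned unmerged as the EP region.
    """
    if u is None:
        u = max(8, round(box.height / 2))
    seed = None
    try:
        seed = seed_region(region_map, box.center, u, "brightest")
    except NoSeedError as exc:
        raise NoEpiglottisRegionError(str(exc)) from exc
    info = region_map.regions[seed]
    if not box.contains_region(info):
        mask = region_map.mask(seed)
        return EPRegion(mask=mask, anchor=ep_anchor(mask), seed_overflowed_box=True)
    res = rpa_merge(
        region_map,
        seed,
        admissible=box.contains_region,
        weight_fn=lambda r: 0.0,
    )
    return EPRegion(mask=res.mask, anchor=ep_anchor(res.mask))


def ep_anchor(ep_mask: np.ndarray) -> EPAnchor:
    """Anchor points of an EP mask.

    ρ = the EP pixel with the maximum row (ties → smallest column); τ = the
    EP edge pixel in ρ's column with the minimum row.  Y_e = row(τ).
    """
    ep_mask = np.asarray(ep_mask, bool)
    rows, cols = np.nonzero(ep_mask)
    if rows.size == 0:
        raise ValueError("empty EP mask has no anchor")
    y_rho = int(rows.max())
    x_rho = int(cols[rows == y_rho].min())
    edge = boundary_edge(ep_mask)
    edge_rows = np.nonzero(edge[:, x_rho])[0]
    y_e = int(edge_rows.min())
    return EPAnchor(x_rho=x_rho, y_rho=y_rho, y_e=y_e)


def merge_ae_region(
    region_map: RegionMap,
    anchor: EPAnchor,
    h: int | None = None,
    config: RPAConfig = RPAConfig(),
) -> AERegion:
    """Merge the airway field of view (AE region) above the epiglottis.

    Seeds with the darkest admissible region in an h×h window centered at
    (x_ρ, Y_e/2); default h = max(4, round(Y_e/4)).  Admissible regions lie
    entirely above the epiglottis top edge (max row <= Y_e); the positional
    weight w_j = ȳ_j − Y_e/2 favors pieces near the epiglottis.  An empty
    result (area 0) signals complete obstruction — it is a valid outcome,
    not an error.
    """
    shape = region_map.shape
    y_e = anchor.y_e
    if y_e < 4:
        return AERegion(mask=np.zeros(shape, bool))
    if h is None:
        h = max(4, round(y_e / 4))

    def admissible(r: RegionInfo) -> bool:
        return r.max_row <= y_e

    try:
        seed = seed_region(
            region_map,
            (anchor.x_rho, y_e // 2),
            h,
            "darkest",
            admissible=admissible,
        )
    except NoSeedError:
        return AERegion(mask=np.zeros(shape, bool))
    res = rpa_merge(
        region_map,
        seed,
        admissible=admissible,
        weight_fn=lambda r: region_weight(r, y_e, config),
    )
    return AERegion(mask=res.mask, trace=res)
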