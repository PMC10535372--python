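from __future__ import annotations

import numpy as np
import pytest

from epifov.quantize import QuantizedImage, label_regions


def region_map_from_ids(id_raster: np.ndarray):
    """Build a RegionMap whose regions are exactly the distinct-id cells.

    Each id gets its own palette color so labeling cannot merge cells; the
    returned map's region ids are the 1-based labels assigned by
    label_regions, with ``id_of[cell_value]`` giving the mapping.
    """
    id_raster = np.asarray(id_raster)
    values = np.unique(id_raster)
    palette = np.array(
        [[(37 * (i + 1)) % 256, (91 * (i + 1)) % 256, (53 * (i + 1)) % 256]
         for i in range(len(values))],
        np.uint8,
    )
    lut = {v: i for i, v in enumerate(values)}
    labels = np.vectorize(lut.get)(id_raster)
    qimg = QuantizedImage(labels=labels, palette=palette, q=len(values))
    return label_regions(qimg)


def random_partition(rng: np.random.Generator, shape=(16, 16), k=6) -> np.ndarray:
    """Partition a grid into <= k connected cells by random multi-source
    growth (4-connected), so every cell is a valid region."""
    h, w = shape
    out = np.full(shape, -1, int)
    k = int(rng.integers(2, k + 1))
    flat = rng.choice(h * w, size=k, replace=False)
    frontier = []
    for cid, f in enumerate(flat):
        out[f // w, f % w] = cid
        frontier.append((f // w, f % w))
    while frontier:
        i = int(rng.integers(len(frontier)))
        r, c = frontier[i]
        grown = False
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and out[rr, cc] == -1:
                out[rr, cc] = out[r, c]
                frontier.append((rr, cc))
                grown = True
                break
        if not grown:
            frontier.pop(i)
    return out


@pytest.fixture(scope="session")
def clean_phantom():
    """Small noise-free phantom with breathing, one occlusion, one slip gap."""
    from epifov.synthetic import PhantomConfig, generate_sequence

    config = PhantomConfig(
        width=320,
        height=240,
        n_frames=30,
        ep_center=(160, 185),
        ep_axes=(75, 40),
        airway_center=(160, 75),
        baseline_area=4500,
        breathing_period=20,
        occlusions=((12, 15, 1.0),),
        slip_intervals=((20, 23),),
        noise_sigma=0.0,
        seed=7,
    )
    frames, gt = generate_sequence(config)
    return config, frames, gt
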