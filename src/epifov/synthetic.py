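"""Endoscopy-like phantom sequences with exact ground truth.

Real sleep-endoscopy recordings of epiglottic collapse are not publicly
shareable, so every stage of the pipeline is exercised on phantoms that
emulate the structure such frames have: a mid-tone pharyngeal-wall
background, a bright convex epiglottis blob in the lower image half, and a
dark airway opening above the epiglottis top edge whose pixel area follows
a programmed schedule (sinusoidal breathing modulation plus occlusion
episodes), with optional Gaussian sensor noise and scope-slip gaps where
the epiglottis leaves the frame.

The airway blob is rendered by taking exactly the scheduled number of
pixels closest to the blob center under an elliptical norm, so the ground
truth area is exact by construction (not merely within a rasterization
tolerance).  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PhantomConfig",
    "FrameTruth",
    "GroundTruth",
    "generate_sequence",
    "scheduled_areas",
    "rle_encode",
    "rle_decode",
    "write_ground_truth",
    "load_ground_truth",
    "write_frames",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of a phantom sequence.

    Defaults mirror a 640×480 rhino-laryngoscope recording: ~18 kpx open
    airway with a 15% breathing swing over 60 frames (2 s at 30 fps) and
    mild sensor noise (σ = 4 gray levels) that survives q = 6 quantization.
    """

    width: int = 640
    height: int = 480
    n_frames: int = 100
    # epiglottis ellipse (bright, lower half)
    ep_center: tuple[int, int] = (320, 370)  # (x, y)
    ep_axes: tuple[int, int] = (150, 80)  # (semi-x, semi-y)
    ep_color: tuple[int, int, int] = (205, 185, 175)
    # airway blob (dark, above the epiglottis top edge)
    airway_center: tuple[int, int] = (320, 150)
    airway_aspect: float = 2.0  # width/height of the elliptical norm
    airway_color: tuple[int, int, int] = (25, 22, 30)
    #: gray levels added from the blob center to its rim (depth shading of
    #: the airway lumen — the opening looks darkest at its deepest point)
    airway_shading: float = 25.0
    #: stress option, outside the single-blob contract: extra lumen lobes
    #: as (dx, dy, aspect) offsets from airway_center, giving the opening an
    #: irregular multi-lobed outline
    airway_lobes: tuple[tuple[int, int, float], ...] = ()
    background: tuple[int, int, int] = (120, 110, 115)
    # airway-area schedule
    baseline_area: int = 18_000
    breathing_amplitude: float = 0.15
    breathing_period: int = 60
    occlusions: tuple[tuple[int, int, float], ...] = ()  # (start, end, depth)
    # frame-level events (1-based inclusive intervals)
    slip_intervals: tuple[tuple[int, int], ...] = ()
    interference_intervals: tuple[tuple[int, int], ...] = ()
    #: radial darkening of the pharyngeal-wall background toward the image
    #: corners (fraction removed at the corner), as endoscope optics produce;
    #: the localized epiglottis/airway blobs keep their nominal colors
    vignette: float = 0.45
    #: amplitude (gray levels) of smooth static mottling on the wall,
    #: emulating mucosal texture; 0 disables
    wall_texture: float = 10.0
    #: spatial scale (px) of the mottling
    wall_texture_scale: float = 12.0
    noise_sigma: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1 or self.width < 1 or self.height < 1:
            raise ValueError("raster and frame count must be positive")
        for s, e, d in self.occlusions:
            if not (0.0 <= d <= 1.0):
                raise ValueError(f"occlusion depth must be in [0,1], got {d}")
            if not (1 <= s <= e <= self.n_frames):
                raise ValueError(f"occlusion interval ({s},{e}) out of range")
        for s, e in self.slip_intervals + self.interference_intervals:
            if not (1 <= s <= e <= self.n_frames):
                raise ValueError(f"interval ({s},{e}) out of frame range")
        # quick single-lobe fit estimate (the exact pixel-level check runs
        # at render time and also covers multi-lobe stress scenes)
        if self.airway_lobes:
            return
        a_max = max(scheduled_areas(self), default=0)
        ay = np.sqrt(a_max * self.airway_aspect / np.pi) / self.airway_aspect
        ax = ay * self.airway_aspect
        cx, cy = self.airway_center
        ep_top = self.ep_center[1] - self.ep_axes[1]
        if a_max > 0 and (
            cy - ay < 0
            or cy + ay >= ep_top
            or cx - ax < 0
            or cx + ax >= self.width
        ):
            raise ValueError(
                "impossible schedule: airway blob of area "
                f"{a_max} does not fit above the epiglottis top edge"
            )


def scheduled_areas(config: PhantomConfig) -> list[int]:
    """Programmed airway pixel area a*_n for every frame (0 on slip frames)."""
    areas = []
    for n in range(1, config.n_frames + 1):
        if _in(n, config.slip_intervals):
            areas.append(0)
            continue
        a = config.baseline_area * (
            1.0
            + config.breathing_amplitude
            * np.sin(2.0 * np.pi * (n - 1) / config.breathing_period)
        )
        for s, e, depth in config.occlusions:
            if s <= n <= e:
                a *= 1.0 - depth
        areas.append(max(0, int(round(a))))
    return areas


def _in(n: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(a <= n <= b for a, b in intervals)


@dataclass
class FrameTruth:
    n: int
    status: str  # normal | slip | occluded | interference
    box: tuple[int, int, int, int] | None  # (x, y, w, h)
    area: int
    ep_mask: np.ndarray
    ae_mask: np.ndarray


@dataclass
class GroundTruth:
    shape: tuple[int, int]
    frames: list[FrameTruth]
    periods: list[tuple[int, int]]
    true_ratios: list[float | None] = field(default_factory=list)

    @property
    def areas(self) -> list[int]:
        return [f.area for f in self.frames]


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    cx, cy = center
    ax, ay = axes
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def _true_periods(statuses: list[str]) -> list[tuple[int, int]]:
    periods = []
    start = None
    for i, s in enumerate(statuses):
        present = s != "slip"
        n = i + 1
        if present and start is None:
            start = n
        elif not present and start is not None:
            periods.append((start, n - 1))
            start = None
    if start is not None:
        periods.append((start, len(statuses)))
    return periods


def generate_sequence(config: PhantomConfig) -> tuple[list[np.ndarray], GroundTruth]:
    """Render the phantom frames and their exact ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    areas = scheduled_areas(config)

    ep_mask = _ellipse_mask((h, w), config.ep_center, config.ep_axes)
    rows, cols = np.nonzero(ep_mask)
    box = (
        int(cols.min()),
        int(rows.min()),
        int(cols.max() - cols.min() + 1),
        int(rows.max() - rows.min() + 1),
    )

    # fixed elliptical-norm pixel order around the airway center: taking the
    # first a pixels renders a connected blob with exactly a pixels
    yy, xx = np.mgrid[:h, :w]
    cx, cy = config.airway_center
    norms = [((xx - cx) / config.airway_aspect) ** 2 + (yy - cy) ** 2]
    for dx, dy, aspect in config.airway_lobes:
        norms.append(((xx - cx - dx) / aspect) ** 2 + (yy - cy - dy) ** 2)
    d = np.min(norms, axis=0)
    order = np.argsort(d.ravel(), kind="stable")

    # direct fit check: the largest scheduled blob must stay strictly above
    # the epiglottis top edge and inside the raster interior
    a_max = max(areas, default=0)
    if a_max > 0:
        sel_rows = order[:a_max] // w
        sel_cols = order[:a_max] % w
        ep_top = config.ep_center[1] - config.ep_axes[1]
        if (
            sel_rows.max() >= ep_top
            or sel_rows.min() < 1
            or sel_cols.min() < 1
            or sel_cols.max() >= w - 1
        ):
            raise ValueError(
                "impossible schedule: airway blob of area "
                f"{a_max} does not fit above the epiglottis top edge"
            )

    # endoscope-like vignetting of the wall: radial quadratic falloff
    r2 = ((xx - w / 2) / (w / 2)) ** 2 + ((yy - h / 2) / (h / 2)) ** 2
    vignette_map = 1.0 - config.vignette * r2 / 2.0
    # static mucosal mottling: smoothed white noise, fixed over the sequence
    if config.wall_texture > 0:
        from scipy.ndimage import gaussian_filter

        field = gaussian_filter(
            rng.standard_normal((h, w)), config.wall_texture_scale
        )
        field /= max(1e-9, np.abs(field).max())
        texture_map = config.wall_texture * field
    else:
        texture_map = np.zeros((h, w))

    empty = np.zeros((h, w), bool)
    frames: list[np.ndarray] = []
    truths: list[FrameTruth] = []
    for n in range(1, config.n_frames + 1):
        slip = _in(n, config.slip_intervals)
        base = np.empty((h, w, 3), np.float64)
        base[:] = config.background
        base *= vignette_map[:, :, None]
        base += texture_map[:, :, None]
        if slip:
            # scope moved: scene shifts, epiglottis out of frame
            ae = empty
            shifted = np.zeros((h, w), bool)
            flat = order[: max(0, config.baseline_area)]
            shifted.ravel()[flat] = True
            shifted = np.roll(shifted, (60, 45), axis=(0, 1))
            base[shifted] = config.airway_color
            fr_box = None
            ep = empty
            status = "slip"
        else:
            a = areas[n - 1]
            ae = np.zeros((h, w), bool)
            if a > 0:
                ae.ravel()[order[:a]] = True
            base[ep_mask] = config.ep_color
            base[ae] = config.airway_color
            if a > 0 and config.airway_shading > 0:
                # lumen depth shading: darkest at the blob center, rising
                # toward its rim
                d_sel = d[ae]
                rel = np.sqrt(d_sel / d_sel.max()) if d_sel.max() > 0 else d_sel
                base[ae] += (config.airway_shading * rel)[:, None]
            ep = ep_mask
            fr_box = box
            if _in(n, config.interference_intervals):
                status = "interference"
            elif a == 0:
                status = "occluded"
            else:
                status = "normal"
        if config.noise_sigma > 0:
            base += rng.normal(0.0, config.noise_sigma, size=base.shape)
        frames.append(np.clip(np.round(base), 0, 255).astype(np.uint8))
        truths.append(
            FrameTruth(
                n=n,
                status=status,
                box=fr_box,
                area=0 if slip else areas[n - 1],
                ep_mask=ep,
                ae_mask=ae,
            )
        )

    periods = _true_periods([t.status for t in truths])
    ratios: list[float | None] = [None] * config.n_frames
    for s, e in periods:
        seg = areas[s - 1 : e]
        amax = max(seg)
        if amax > 0:
            for i, a in enumerate(seg, start=s):
                ratios[i - 1] = 100.0 * (amax - a) / amax
    return frames, GroundTruth(
        shape=(h, w), frames=truths, periods=periods, true_ratios=ratios
    )


# ---------------------------------------------------------------------------
# ground-truth serialization (JSON with run-length encoded masks)
# ---------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> list[list[int]]:
    """Run-length encode a binary mask (row-major [start, length] pairs)."""
    flat = np.asarray(mask, bool).ravel()
    if flat.size == 0:
        return []
    changes = np.nonzero(np.diff(flat))[0] + 1
    bounds = np.concatenate([[0], changes, [flat.size]])
    runs = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if flat[s]:
            runs.append([int(s), int(e - s)])
    return runs


def rle_decode(runs: Sequence[Sequence[int]], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(shape[0] * shape[1], bool)
    for start, length in runs:
        flat[start : start + length] = True
    return flat.reshape(shape)


def write_ground_truth(gt: GroundTruth, path) -> None:
    doc = {
        "shape": list(gt.shape),
        "periods": [list(p) for p in gt.periods],
        "true_ratios": gt.true_ratios,
        "frames": [
            {
                "n": f.n,
                "status": f.status,
                "box": list(f.box) if f.box else None,
                "area": f.area,
                "ep_rle": rle_encode(f.ep_mask),
                "ae_rle": rle_encode(f.ae_mask),
            }
            for f in gt.frames
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_ground_truth(path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    shape = tuple(doc["shape"])
    frames = [
        FrameTruth(
            n=f["n"],
            status=f["status"],
            box=tuple(f["box"]) if f["box"] else None,
            area=f["area"],
            ep_mask=rle_decode(f["ep_rle"], shape),
            ae_mask=rle_decode(f["ae_rle"], shape),
        )
        for f in doc["frames"]
    ]
    return GroundTruth(
        shape=shape,
        frames=frames,
        periods=[tuple(p) for p in doc["periods"]],
        true_ratios=doc["true_ratios"],
    )


def write_frames(frames: Sequence[np.ndarray], out_dir) -> list[Path]:
    """Write frames as zero-padded numbered PNGs ready for ``analyze``."""
    import imageio.v2 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    digits = max(4, len(str(len(frames))))
    for i, fr in enumerate(frames, start=1):
        p = out / f"frame_{i:0{digits}d}.png"
        iio.imwrite(p, fr)
        paths.append(p)
    return paths
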