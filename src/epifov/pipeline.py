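"""Per-frame analysis, period segmentation, anomaly filtering, ratios.

The endoscope is assumed stationary while the epiglottis stays in view, so
frames are grouped into *periods* — maximal runs of consecutive frames with
a detected epiglottis.  Within a period the largest observed airway
field-of-view area serves as the unobstructed reference, and the per-frame
obstruction ratio is

    O_mn (%) = 100 · (max|A_mn| − |A_mn|) / max|A_mn|

reported at 0.1% granularity.  Two anomaly rules run before the period
maximum is taken: a frame whose airway measurement disagrees with both of
its immediate neighbors (which saw no epiglottis or a complete
obstruction), and a single-frame spike whose backward differences
sign-alternate with both magnitudes above a threshold ε.  Abnormal frames,
operator-marked interference intervals, and frames without a detected
epiglottis carry no ratio.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detector import DEFAULT_CONF_MIN, DetectionRecord, select_box
from .quantize import label_regions, median_cut_quantize
from .rpa import (
    AERegion,
    BoundingBox,
    EPRegion,
    NoEpiglottisRegionError,
    RPAConfig,
    merge_ae_region,
    merge_ep_region,
)

__all__ = [
    "Status",
    "FrameResult",
    "Period",
    "ObstructionSeries",
    "AnalysisParams",
    "RunResult",
    "DEFAULT_Q",
    "DEFAULT_EPSILON",
    "round_half_up",
    "segment_periods",
    "analyze_frame",
    "flag_abnormal_neighbors",
    "flag_abnormal_diff",
    "obstruction_ratios",
    "period_average",
    "analyze_sequence",
    "iter_frames",
    "degree_label",
]

logger = logging.getLogger("epifov")

DEFAULT_Q = 6
DEFAULT_EPSILON = 30_000  # px, backward-difference spike threshold


class Status:
    OK = "ok"
    NO_EPIGLOTTIS = "no_epiglottis"
    COMPLETE_OBSTRUCTION = "complete_obstruction"
    ABNORMAL = "abnormal"
    INTERFERENCE_EXCLUDED = "interference_excluded"


#: statuses that block a neighbor per the first anomaly rule
_BLOCKERS = {Status.NO_EPIGLOTTIS, Status.COMPLETE_OBSTRUCTION}


@dataclass
class FrameResult:
    n: int
    detected: bool
    status: str
    omega: int = 0  # |A| in pixels
    ep: EPRegion | None = None
    ae: AERegion | None = None
    period: int | None = None
    ratio: float | None = None


@dataclass(frozen=True)
class Period:
    m: int
    start: int  # first frame index (1-based, inclusive)
    end: int  # last frame index (inclusive)
    max_area: int = 0

    def contains(self, n: int) -> bool:
        return self.start <= n <= self.end


@dataclass
class ObstructionSeries:
    """Per-frame ratios (None where no ratio is defined) plus diagnostics."""

    frames: list[int]
    ratios: list[float | None]
    statuses: list[str]
    periods: list[Period]
    omega: list[int]
    backward_diff: list[float]

    def ratio_at(self, n: int) -> float | None:
        return self.ratios[self.frames.index(n)]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (49.95 → 50.0), matching printed precision."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(quantum, ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# period segmentation
# ---------------------------------------------------------------------------

def segment_periods(detected: Sequence[bool], first_frame: int = 1) -> list[Period]:
    """Maximal runs of detected frames, numbered m = 1..M in order."""
    periods: list[Period] = []
    start = None
    for i, flag in enumerate(detected):
        n = first_frame + i
        if flag and start is None:
            start = n
        elif not flag and start is not None:
            periods.append(Period(m=len(periods) + 1, start=start, end=n - 1))
            start = None
    if start is not None:
        periods.append(
            Period(m=len(periods) + 1, start=start, end=first_frame + len(detected) - 1)
        )
    return periods


# ---------------------------------------------------------------------------
# single-frame analysis
# ---------------------------------------------------------------------------

def analyze_frame(
    frame: np.ndarray,
    box: BoundingBox | None,
    n: int = 1,
    q: int = DEFAULT_Q,
    u: int | None = None,
    h: int | None = None,
    rpa_config: RPAConfig = RPAConfig(),
    keep_masks: bool = False,
) -> FrameResult:
    """Quantize → label → EP merge → anchor → AE merge for one frame.

    No box (or no seedable epiglottis region) yields ``no_epiglottis``; a
    detected epiglottis with an empty airway yields ``complete_obstruction``
    with ω = 0.
    """
    if box is None:
        return FrameResult(n=n, detected=False, status=Status.NO_EPIGLOTTIS)
    qimg = median_cut_quantize(frame, q)
    region_map = label_regions(qimg)
    try:
        ep = merge_ep_region(region_map, box, u=u, config=rpa_config)
    except NoEpiglottisRegionError:
        return FrameResult(n=n, detected=False, status=Status.NO_EPIGLOTTIS)
    ae = merge_ae_region(region_map, ep.anchor, h=h, config=rpa_config)
    omega = ae.area
    status = Status.OK if omega > 0 else Status.COMPLETE_OBSTRUCTION
    return FrameResult(
        n=n,
        detected=True,
        status=status,
        omega=omega,
        ep=ep if keep_masks else None,
        ae=ae if keep_masks else None,
    )


# ---------------------------------------------------------------------------
# anomaly rules
# ---------------------------------------------------------------------------

def flag_abnormal_neighbors(results: Sequence[FrameResult]) -> list[bool]:
    """First anomaly rule: a positive airway reading sandwiched between
    frames that saw no epiglottis or a complete obstruction.

    Sequence endpoints are judged by their single neighbor.  Returns a
    per-frame flag list; it does not mutate the results.
    """
    flags = [False] * len(results)
    for i, r in enumerate(results):
        if r.omega <= 0:
            continue
        neighbors = []
        if i > 0:
            neighbors.append(results[i - 1].status)
        if i < len(results) - 1:
            neighbors.append(results[i + 1].status)
        if neighbors and all(s in _BLOCKERS for s in neighbors):
            flags[i] = True
    return flags


def flag_abnormal_diff(omega: Sequence[float], epsilon: float = DEFAULT_EPSILON) -> list[bool]:
    """Second anomaly rule: single-frame spikes in the backward difference.

    With ω′_n = ω_n − ω_{n−1}, frame n is abnormal when (ω′_n, ω′_{n+1})
    sign-alternate (+,− or −,+) and both magnitudes exceed ε.  Monotone
    ramps never alternate and are never flagged.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    flags = [False] * len(omega)
    diffs = [omega[i] - omega[i - 1] for i in range(1, len(omega))]
    for i in range(len(diffs) - 1):
        d0, d1 = diffs[i], diffs[i + 1]
        if (d0 > 0 > d1 or d0 < 0 < d1) and abs(d0) > epsilon and abs(d1) > epsilon:
            flags[i + 1] = True  # diffs[i] = ω_{i+1} − ω_i → frame index i+1
    return flags


# ---------------------------------------------------------------------------
# obstruction ratios
# ---------------------------------------------------------------------------

def _in_intervals(n: int, intervals: Iterable[tuple[int, int]]) -> bool:
    return any(a <= n <= b for a, b in intervals)


def obstruction_ratios(
    results: Sequence[FrameResult],
    periods: Sequence[Period],
    exclusions: Sequence[tuple[int, int]] = (),
) -> ObstructionSeries:
    """Eq.-style per-frame ratio series with the period maximum as reference.

    Each period's maximum is taken over frames that are neither abnormal
    nor inside an exclusion interval; ratios are rounded half-up to 0.1.
    Complete-obstruction frames report 100.0; abnormal / excluded /
    no-epiglottis frames carry no ratio.  A period whose maximum is 0
    yields no ratios (warning logged).
    """
    by_n = {r.n: r for r in results}
    updated_periods: list[Period] = []
    ratios: list[float | None] = [None] * len(results)
    for p in periods:
        members = [by_n[n] for n in range(p.start, p.end + 1) if n in by_n]
        usable = [
            r
            for r in members
            if r.status in (Status.OK, Status.COMPLETE_OBSTRUCTION)
            and not _in_intervals(r.n, exclusions)
        ]
        max_area = max((r.omega for r in usable), default=0)
        updated_periods.append(Period(m=p.m, start=p.start, end=p.end, max_area=max_area))
        for r in members:
            r.period = p.m
        if max_area <= 0:
            logger.warning(
                "period m=%d (%d-%d): maximum airway area is 0; no ratios computed",
                p.m, p.start, p.end,
            )
            continue
        for r in usable:
            if r.status == Status.COMPLETE_OBSTRUCTION:
                r.ratio = 100.0
            else:
                r.ratio = round_half_up(100.0 * (max_area - r.omega) / max_area)
    for i, r in enumerate(results):
        ratios[i] = r.ratio
    omega = [r.omega for r in results]
    diffs = [0.0] + [float(omega[i] - omega[i - 1]) for i in range(1, len(omega))]
    return ObstructionSeries(
        frames=[r.n for r in results],
        ratios=ratios,
        statuses=[r.status for r in results],
        periods=updated_periods,
        omega=omega,
        backward_diff=diffs,
    )


def period_average(series: ObstructionSeries, interval: tuple[int, int]) -> float:
    """Mean obstruction ratio ω̄ over ratio-carrying frames of an interval."""
    a, b = interval
    vals = [
        r
        for n, r in zip(series.frames, series.ratios)
        if a <= n <= b and r is not None
    ]
    if not vals:
        raise ValueError(f"no ratio-carrying frames in interval {interval}")
    return round_half_up(sum(vals) / len(vals))


def degree_label(ratio: float) -> int:
    """Legacy clinical three-band grading of an obstruction ratio.

    0: 0-49% (no obstruction), 1: 50-75% (partial), 2: 76-100% (complete).
    """
    if ratio < 50:
        return 0
    if ratio < 76:
        return 1
    return 2


# ---------------------------------------------------------------------------
# sequence orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisParams:
    q: int = DEFAULT_Q
    epsilon: float = DEFAULT_EPSILON
    conf_min: float = DEFAULT_CONF_MIN
    u: int | None = None
    h: int | None = None
    exclusions: tuple[tuple[int, int], ...] = ()
    rpa: RPAConfig = RPAConfig()


@dataclass
class RunResult:
    results: list[FrameResult]
    series: ObstructionSeries
    params: AnalysisParams

    def frame_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": [r.n for r in self.results],
                "detected": [r.detected for r in self.results],
                "status": [r.status for r in self.results],
                "omega": [r.omega for r in self.results],
                "period": [r.period for r in self.results],
                "ratio": [r.ratio for r in self.results],
            }
        )

    def period_table(self) -> pd.DataFrame:
        rows = []
        for p in self.series.periods:
            carried = [
                r
                for n, r in zip(self.series.frames, self.series.ratios)
                if p.contains(n) and r is not None
            ]
            rows.append(
                {
                    "m": p.m,
                    "start": p.start,
                    "end": p.end,
                    "max_area": p.max_area,
                    "mean_ratio": round_half_up(sum(carried) / len(carried))
                    if carried
                    else None,
                }
            )
        return pd.DataFrame(rows)


def analyze_sequence(
    frames: Iterable[tuple[int, np.ndarray]],
    detections: Mapping[int, DetectionRecord],
    params: AnalysisParams = AnalysisParams(),
    keep_masks: bool = False,
) -> RunResult:
    """Run the full per-frame pipeline over a (frame_index, image) stream.

    Order of post-processing: interference exclusions → neighbor anomaly
    rule → backward-difference spike rule → period maxima → ratio series.
    """
    results: list[FrameResult] = []
    for n, image in frames:
        t0 = time.perf_counter()
        box = select_box(detections.get(n), conf_min=params.conf_min)
        r = analyze_frame(
            image,
            box,
            n=n,
            q=params.q,
            u=params.u,
            h=params.h,
            rpa_config=params.rpa,
            keep_masks=keep_masks,
        )
        results.append(r)
        logger.info(
            "frame %d: status=%s omega=%d (%.3f s)",
            n, r.status, r.omega, time.perf_counter() - t0,
        )

    first = results[0].n if results else 1
    periods = segment_periods([r.detected for r in results], first_frame=first)

    for r in results:
        if r.detected and _in_intervals(r.n, params.exclusions):
            r.status = Status.INTERFERENCE_EXCLUDED

    neighbor_flags = flag_abnormal_neighbors(results)
    diff_flags = flag_abnormal_diff([r.omega for r in results], params.epsilon)
    for r, fa, fb in zip(results, neighbor_flags, diff_flags):
        if (fa or fb) and r.status in (Status.OK, Status.COMPLETE_OBSTRUCTION):
            r.status = Status.ABNORMAL

    series = obstruction_ratios(results, periods, params.exclusions)
    return RunResult(results=results, series=series, params=params)


# ---------------------------------------------------------------------------
# frame IO
# ---------------------------------------------------------------------------

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


def iter_frames(path) -> Iterable[tuple[int, np.ndarray]]:
    """Yield 1-based (index, RGB frame) pairs from a directory or video.

    A directory is read as numbered image files in zero-padded numeric
    order; anything else is handed to imageio's video reader (requires an
    available video backend).
    """
    import imageio.v2 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise FileNotFoundError(f"no image files in {path}")
        for i, f in enumerate(files, start=1):
            img = np.asarray(iio.imread(f))
            if img.ndim == 2:
                img = np.stack([img] * 3, axis=-1)
            yield i, img[:, :, :3]
    else:
        try:
            reader = iio.get_reader(path)
        except Exception as exc:  # pragma: no cover - backend-dependent
            raise RuntimeError(
                f"cannot open {path} as video (no backend available); "
                "extract frames to an image directory instead"
            ) from exc
        for i, img in enumerate(reader, start=1):
            yield i, np.asarray(img)[:, :, :3]


def write_reports(run: RunResult, out_dir, metadata: dict | None = None) -> None:
    """Write per-frame CSV, period-summary CSV and run-metadata JSON."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run.frame_table().to_csv(out / "frames.csv", index=False)
    run.period_table().to_csv(out / "periods.csv", index=False)
    meta = {
        "q": run.params.q,
        "epsilon": run.params.epsilon,
        "conf_min": run.params.conf_min,
        "u": run.params.u,
        "h": run.params.h,
        "exclusions": list(map(list, run.params.exclusions)),
    }
    if metadata:
        meta.update(metadata)
    (out / "run.json").write_text(json.dumps(meta, indent=2))


def plot_series(series: ObstructionSeries, path) -> None:
    """Chart ω and O against the frame index (matplotlib, Agg-safe)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax1 = plt.subplots(figsize=(10, 4))
    ax1.plot(series.frames, series.omega, color="tab:blue", lw=1, label="ω (px)")
    ax1.set_xlabel("frame index n")
    ax1.set_ylabel("AE-region area ω (px)", color="tab:blue")
    ax2 = ax1.twinx()
    xs = [n for n, r in zip(series.frames, series.ratios) if r is not None]
    ys = [r for r in series.ratios if r is not None]
    ax2.bar(xs, ys, color="tab:red", alpha=0.4, label="O (%)")
    ax2.set_ylabel("obstruction ratio O (%)", color="tab:red")
    ax2.set_ylim(0, 100)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
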