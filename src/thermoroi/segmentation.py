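"""Seeded region growing (SRG) detection of hot supraclavicular ROIs.

The detector expands a region from the hottest pixel of a pre-defined search
window. At each step it considers the frontier ``H`` — every unallocated
pixel 8-adjacent to the current region — and admits the frontier pixel whose
temperature deviation from the *running* region mean,

    delta(x) = | T(x) - mean_{y in region} T(y) |,

is smallest, provided ``delta <= T_t`` (the admission tolerance, non-strict).
Growth stops when the best frontier deviation exceeds ``T_t``, the frontier
empties, or a size cap is reached. Because the stopping rule keys on a sharp
change in the dermal temperature gradient rather than an isotherm, the result
is a single closed 8-connected region, unlike plain top-quartile thresholding
which may select scattered pixel clusters (provided here as a baseline).

Tie-breaking is deterministic: among frontier pixels with equal deviation the
smallest (row, col) in row-major order is admitted; equal-temperature seed
candidates resolve the same way.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import MissingFrameWarning, SegmentationError, ShapeError
from .io import ThermalFrame, ThermalSequence

__all__ = [
    "SearchWindow",
    "SegmentationParams",
    "Region",
    "FrameSegmentation",
    "SequenceSegmentation",
    "select_seed",
    "grow_region",
    "segment_sequence",
    "threshold_segment",
    "select_tolerance",
]

_NEIGHBORS_8 = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)


@dataclass(frozen=True)
class SearchWindow:
    """Rectangular pixel bounds (inclusive start, exclusive stop) of one
    supraclavicular search area, labelled by body side."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    side: str = "left"

    def __post_init__(self):
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ShapeError("search window must be non-empty")
        if self.row_start < 0 or self.col_start < 0:
            raise ShapeError("search window bounds must be non-negative")

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_start, self.row_stop), slice(
            self.col_start, self.col_stop
        )

    @property
    def n_pixels(self) -> int:
        return (self.row_stop - self.row_start) * (self.col_stop - self.col_start)

    def contains(self, row: int, col: int) -> bool:
        return (
            self.row_start <= row < self.row_stop
            and self.col_start <= col < self.col_stop
        )

    def check_frame(self, frame: ThermalFrame) -> None:
        if self.row_stop > frame.height or self.col_stop > frame.width:
            raise ShapeError(
                f"window {self} exceeds frame bounds {frame.shape}"
            )

    @classmethod
    def full_frame(cls, frame: ThermalFrame, side: str = "left") -> "SearchWindow":
        return cls(0, frame.height, 0, frame.width, side=side)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the region grower.

    t_t
        Admission tolerance in °C: growth stops once the closest frontier
        pixel deviates from the region mean by more than this. Optimised per
        subject in practice; :func:`select_tolerance` offers an automatic
        surrogate.
    seed_region_radius
        Chebyshev radius of the initial seed neighbourhood (default 1, i.e. a
        3x3 block of valid pixels) so the starting mean is stable.
    seed_tolerance
        Optional thermal-homogeneity condition on the seed block: when set,
        only neighbours within this many °C of the seed temperature join the
        initial region. Keeps the starting mean anchored to the hot region
        when the hottest pixel sits on the region's edge (where an
        unconditioned block would mix in cooler across-the-boundary pixels
        and growth could leak down the surrounding gradient). Deliberately a
        separate parameter from ``t_t`` so that growth remains monotone in
        ``t_t``: the admission order never depends on ``t_t``, which only
        decides where growth stops.
    max_region_fraction
        Cap on region size as a fraction of the search window, guarding
        against runaway growth on low-contrast frames.
    """

    t_t: float
    seed_region_radius: int = 1
    seed_tolerance: float | None = None
    max_region_fraction: float = 0.5
    connectivity: int = 8  # fixed; field kept for explicitness

    def __post_init__(self):
        if self.t_t < 0:
            raise ValueError("t_t must be >= 0")
        if self.seed_region_radius < 0:
            raise ValueError("seed_region_radius must be >= 0")
        if self.seed_tolerance is not None and self.seed_tolerance < 0:
            raise ValueError("seed_tolerance must be >= 0")
        if not (0 < self.max_region_fraction <= 1):
            raise ValueError("max_region_fraction must be in (0, 1]")
        if self.connectivity != 8:
            raise ValueError("only 8-connectivity is supported")


@dataclass
class Region:
    """A grown region: member pixel set with its running mean temperature."""

    pixels: set[tuple[int, int]]
    mean_temperature: float
    shape: tuple[int, int]

    @property
    def pixel_count(self) -> int:
        return len(self.pixels)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        if self.pixels:
            rows, cols = zip(*self.pixels)
            m[list(rows), list(cols)] = True
        return m


@dataclass
class FrameSegmentation:
    """Per-frame detection result: mask, count, mean ROI temperature, seed."""

    mask: np.ndarray
    pixel_count: int
    mean_temperature_c: float
    seed: tuple[int, int]
    t_t: float
    frame_index: int = 0


@dataclass
class SequenceSegmentation:
    """Per-frame results plus the sequence averages the quantification uses."""

    frames: list[FrameSegmentation | None]
    mean_pixel_count: float
    mean_roi_temperature_c: float

    @property
    def n_frames_processed(self) -> int:
        return sum(f is not None for f in self.frames)


def _valid_grid(
    frame: ThermalFrame, exclude: np.ndarray | None
) -> np.ndarray:
    valid = frame.valid_mask
    if exclude is not None:
        exclude = np.asarray(exclude, dtype=bool)
        if exclude.shape != frame.shape:
            raise ShapeError("exclude mask shape must match the frame")
        valid = valid & ~exclude
    return valid


def select_seed(
    frame: ThermalFrame,
    window: SearchWindow,
    exclude: np.ndarray | None = None,
) -> tuple[int, int]:
    """Hottest valid pixel inside the search window.

    Deterministic under ties: the first maximum in row-major order (smallest
    row, then smallest column) is returned.
    """
    window.check_frame(frame)
    valid = _valid_grid(frame, exclude)
    rs, cs = window.slices
    sub = np.where(valid[rs, cs], frame.values[rs, cs], -np.inf)
    if not np.isfinite(sub).any():
        raise SegmentationError(
            f"no valid pixel in {window.side} window {window}"
        )
    flat = int(np.argmax(sub))  # argmax returns the first max row-major
    r, c = divmod(flat, sub.shape[1])
    return (r + window.row_start, c + window.col_start)


def grow_region(
    frame: ThermalFrame,
    seed: tuple[int, int],
    params: SegmentationParams,
    window: SearchWindow | None = None,
    exclude: np.ndarray | None = None,
) -> Region:
    """Grow an 8-connected region from ``seed`` by minimum-deviation admission.

    The region starts as the valid pixels within Chebyshev radius
    ``params.seed_region_radius`` of the seed (invalid pixels shrink the seed
    neighbourhood); with ``params.seed_tolerance`` set, the block is further
    restricted to pixels thermally homogeneous with the seed. The grower then
    repeatedly admits the frontier pixel closest in temperature to the
    current region mean while that deviation stays within ``params.t_t``; the
    mean is updated after every admission. Growth is confined to ``window``
    when one is given.
    """
    if window is None:
        window = SearchWindow.full_frame(frame)
    else:
        window.check_frame(frame)
    sr, sc = seed
    if not (0 <= sr < frame.height and 0 <= sc < frame.width):
        raise SegmentationError(f"seed {seed} outside frame bounds {frame.shape}")
    if not window.contains(sr, sc):
        raise SegmentationError(f"seed {seed} outside search window {window}")
    valid = _valid_grid(frame, exclude)
    if not valid[sr, sc]:
        raise SegmentationError(f"seed {seed} is an invalid pixel")

    values = frame.values
    rad = params.seed_region_radius
    seed_temp = values[sr, sc]
    seed_tol = math.inf if params.seed_tolerance is None else params.seed_tolerance
    region: set[tuple[int, int]] = set()
    for r in range(max(window.row_start, sr - rad), min(window.row_stop, sr + rad + 1)):
        for c in range(
            max(window.col_start, sc - rad), min(window.col_stop, sc + rad + 1)
        ):
            if valid[r, c] and abs(values[r, c] - seed_temp) <= seed_tol:
                region.add((r, c))
    # exactly-rounded running sum (fsum is order-independent), so equal-delta
    # ties resolve purely by the documented (row, col) rule
    temps: list[float] = [float(values[p]) for p in region]
    count = len(region)
    max_pixels = max(1, int(math.floor(params.max_region_fraction * window.n_pixels)))

    def neighbors(r: int, c: int):
        for dr, dc in _NEIGHBORS_8:
            rr, cc = r + dr, c + dc
            if window.contains(rr, cc) and valid[rr, cc]:
                yield rr, cc

    frontier: dict[tuple[int, int], float] = {}
    for r, c in region:
        for p in neighbors(r, c):
            if p not in region:
                frontier[p] = values[p]

    while frontier and count < max_pixels:
        mean = math.fsum(temps) / count
        best = min(frontier.items(), key=lambda kv: (abs(kv[1] - mean), kv[0]))
        (r, c), temp = best
        if abs(temp - mean) > params.t_t:
            break
        del frontier[(r, c)]
        region.add((r, c))
        temps.append(float(temp))
        count += 1
        for p in neighbors(r, c):
            if p not in region:
                frontier[p] = values[p]

    return Region(
        pixels=region, mean_temperature=math.fsum(temps) / count, shape=frame.shape
    )


def segment_sequence(
    seq: ThermalSequence,
    window: SearchWindow,
    params: SegmentationParams,
    exclude: np.ndarray | list[np.ndarray] | None = None,
) -> SequenceSegmentation:
    """Segment every frame independently and average the per-frame statistics.

    The seed is re-selected per frame (hottest window pixel). The sequence
    averages are arithmetic means over frames of the per-frame ROI pixel count
    and per-frame mean ROI temperature — matching the 5 s / 150 frame video
    averaging protocol. Unsegmentable frames are recorded as ``None``,
    excluded from the averages, and reported via a warning.
    """
    results: list[FrameSegmentation | None] = []
    counts: list[int] = []
    temps: list[float] = []
    for i, frame in enumerate(seq):
        excl = exclude[i] if isinstance(exclude, list) else exclude
        try:
            seed = select_seed(frame, window, exclude=excl)
            region = grow_region(frame, seed, params, window=window, exclude=excl)
        except SegmentationError as err:
            warnings.warn(
                f"frame {i} unsegmentable ({err}); excluded from averages",
                MissingFrameWarning,
                stacklevel=2,
            )
            results.append(None)
            continue
        fs = FrameSegmentation(
            mask=region.mask(),
            pixel_count=region.pixel_count,
            mean_temperature_c=region.mean_temperature,
            seed=seed,
            t_t=params.t_t,
            frame_index=i,
        )
        results.append(fs)
        counts.append(fs.pixel_count)
        temps.append(fs.mean_temperature_c)
    if not counts:
        raise SegmentationError("no frame in the sequence could be segmented")
    return SequenceSegmentation(
        frames=results,
        mean_pixel_count=float(np.mean(counts)),
        mean_roi_temperature_c=float(np.mean(temps)),
    )


def threshold_segment(
    frame: ThermalFrame,
    window: SearchWindow,
    exclude: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Top-quartile threshold baseline.

    The threshold is the median of the highest 25 % of valid window pixels
    (``ceil(0.25 n)`` of them); every window pixel at or above it is selected.
    Connectivity is deliberately NOT enforced — the scattered clusters this
    produces are the known limitation the region grower addresses.

    Returns the boolean mask (frame-shaped) and the threshold used.
    """
    window.check_frame(frame)
    valid = _valid_grid(frame, exclude)
    rs, cs = window.slices
    sub_valid = valid[rs, cs]
    vals = frame.values[rs, cs][sub_valid]
    n = vals.size
    if n < 4:
        raise SegmentationError(
            f"threshold segmentation needs >= 4 valid window pixels, got {n}"
        )
    k = math.ceil(0.25 * n)
    top = np.sort(vals)[-k:]
    threshold = float(np.median(top))
    mask = np.zeros(frame.shape, dtype=bool)
    mask[rs, cs] = sub_valid & (frame.values[rs, cs] >= threshold)
    return mask, threshold


def select_tolerance(
    frame: ThermalFrame,
    window: SearchWindow,
    grid: np.ndarray | None = None,
    seed_region_radius: int = 1,
    max_region_fraction: float = 0.5,
    exclude: np.ndarray | None = None,
) -> float:
    """Automatic surrogate for per-subject manual tuning of the tolerance.

    Scans a grid of candidate tolerances and returns the midpoint of the
    longest run over which the grown region size stays constant — the flattest
    plateau of the size-versus-tolerance curve, where segmentation is least
    sensitive to the exact tolerance choice. Documented as an extension: the
    original protocol tuned the tolerance manually per subject.
    """
    if grid is None:
        grid = np.round(np.arange(0.05, 2.01, 0.05), 10)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("tolerance grid needs at least 2 values")
    seed = select_seed(frame, window, exclude=exclude)
    sizes = []
    for t in grid:
        params = SegmentationParams(
            t_t=float(t),
            seed_region_radius=seed_region_radius,
            max_region_fraction=max_region_fraction,
        )
        sizes.append(
            grow_region(frame, seed, params, window=window, exclude=exclude).pixel_count
        )
    # longest run of constant size; first such run wins ties
    best_start, best_len = 0, 1
    start = 0
    for i in range(1, len(sizes) + 1):
        if i == len(sizes) or sizes[i] != sizes[start]:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = i
    return float(grid[best_start + best_len // 2])
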