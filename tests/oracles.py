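"""Independent from-scratch reference implementations used only by tests.

The reference region grower below deliberately avoids all incremental
bookkeeping of the production implementation: every iteration it rebuilds the
frontier set and recomputes the region mean and every frontier deviation from
scratch, and it scans candidates in reverse-sorted order so that agreement
with the production grower also demonstrates that region membership does not
depend on frontier iteration order beyond the documented (row, col)
tie-break.
"""

from __future__ import annotations

import math

import numpy as np


def naive_grow_region(
    values: np.ndarray,
    seed: tuple[int, int],
    t_t: float,
    seed_region_radius: int = 1,
    max_region_fraction: float = 0.5,
    seed_tolerance: float | None = None,
) -> set[tuple[int, int]]:
    """Reference seeded region growing over the full frame.

    Semantics: start from the valid pixels within Chebyshev radius
    ``seed_region_radius`` of the seed (restricted to those within
    ``seed_tolerance`` of the seed temperature when given); repeatedly admit
    the frontier pixel (8-adjacent to the region) with the smallest absolute
    deviation from the current region mean, ties broken by smallest
    (row, col), while the deviation stays within ``t_t`` and the region is
    below ``max_region_fraction`` of the frame.
    """
    values = np.asarray(values, dtype=float)
    h, w = values.shape
    sr, sc = seed
    if not np.isfinite(values[sr, sc]):
        raise ValueError("seed is invalid")
    seed_temp = values[sr, sc]
    seed_tol = math.inf if seed_tolerance is None else seed_tolerance
    region = {
        (r, c)
        for r in range(max(0, sr - seed_region_radius), min(h, sr + seed_region_radius + 1))
        for c in range(max(0, sc - seed_region_radius), min(w, sc + seed_region_radius + 1))
        if np.isfinite(values[r, c]) and abs(values[r, c] - seed_temp) <= seed_tol
    }
    max_pixels = max(1, int(math.floor(max_region_fraction * h * w)))

    while len(region) < max_pixels:
        # rebuild the frontier H from scratch
        frontier = set()
        for r, c in region:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < h
                        and 0 <= cc < w
                        and (rr, cc) not in region
                        and np.isfinite(values[rr, cc])
                    ):
                        frontier.add((rr, cc))
        if not frontier:
            break
        mean = math.fsum(float(values[p]) for p in region) / len(region)
        best = None
        for p in sorted(frontier, reverse=True):  # adversarial scan order
            delta = abs(values[p] - mean)
            if best is None or (delta, p) < best:
                best = (delta, p)
        delta, p = best
        if delta > t_t:
            break
        region.add(p)
    return region


def random_small_frame(rng: np.random.Generator) -> np.ndarray:
    """A random frame of size up to 7x7 with occasional invalid pixels and
    deliberate temperature ties (quantized values make ties common)."""
    h = int(rng.integers(2, 8))
    w = int(rng.integers(2, 8))
    vals = rng.integers(300, 360, size=(h, w)).astype(float) / 10.0
    if rng.random() < 0.3:
        n_bad = int(rng.integers(1, max(2, h * w // 4)))
        idx = rng.choice(h * w, size=n_bad, replace=False)
        flat = vals.ravel()
        flat[idx] = np.nan
        vals = flat.reshape(h, w)
    return vals
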