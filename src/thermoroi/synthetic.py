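"""Synthetic thermogram and cohort generation with known ground truth.

Real supraclavicular thermograms from the validation study are not released,
so every downstream stage is exercised on synthetic scenes that reproduce the
features the pipeline keys on: a warm skin background (optionally with a
gentle spatial gradient), one or two hotter contiguous "BAT" plateaus with a
sharp dermal-gradient boundary, four cooler foil-disk fiducials at the known
18 cm x 8 cm spacing, Gaussian pixel noise, and slow rigid pose drift.

The hotspot profile is a flat plateau with a clipped-sigmoid edge: inside the
elliptical boundary the elevation is exactly ``delta_t_c``; outside it follows
the sigmoid tail ``delta_t_c / (1 + exp(e / w))`` of the pixel distance ``e``
past the boundary, so the first exterior pixel already sits at most half the
plateau elevation above background. The region grower's stopping rule keys on
exactly this kind of sharp temperature-gradient change, which a pure Gaussian
bump does not provide. Ground truth (per-frame plateau masks and the exact
pixel-to-metric transform) is returned alongside each sequence.

A separate cohort generator emulates the study design at the subject level:
a mixture of low-BAT non-responders and high-BAT responders whose
cold-stimulated percent change in heat output is drawn from a shifted
distribution, with ground-truth labels for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import FiducialLayout, PlanarTransform, estimate_transform
from .io import ThermalFrame, ThermalSequence

__all__ = [
    "HotspotSpec",
    "SceneSpec",
    "SceneGroundTruth",
    "generate_sequence",
    "generate_cohort",
]


@dataclass(frozen=True)
class HotspotSpec:
    """One elliptical hot plateau over a BAT depot.

    ``delta_t_c`` is the plateau elevation above the local background;
    ``edge_width_px`` controls how fast temperature falls outside the
    elliptical boundary (smaller = sharper dermal gradient).
    """

    center: tuple[float, float]  # (row, col) px
    semi_axes: tuple[float, float] = (10.0, 14.0)  # (row, col) px
    delta_t_c: float = 2.0
    edge_width_px: float = 1.0
    side: str = "left"

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")
        if self.delta_t_c < 0:
            raise ValueError("plateau elevation must be >= 0")
        if self.edge_width_px <= 0:
            raise ValueError("edge width must be positive")


def _default_hotspots() -> tuple[HotspotSpec, ...]:
    return (
        HotspotSpec(center=(100.0, 105.0), side="left"),
        HotspotSpec(center=(100.0, 215.0), side="right"),
    )


def _default_fiducials() -> tuple[tuple[float, float], ...]:
    # 18 cm x 8 cm rectangle rendered at 10 px/cm, centred in a 240x320 frame:
    # upper (trapezius) disks at row 70, lower (subclavicular) at row 150.
    return ((70.0, 70.0), (70.0, 250.0), (150.0, 70.0), (150.0, 250.0))


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic thermogram sequence.

    Defaults emulate the acquisition protocol: a 320x240 thermal camera one
    metre from the chest (about 10 px/cm on the body plane), 30 Hz video,
    ~33 °C background skin, foil fiducials near 29.5 °C, plateaus ~2 °C above
    skin, and camera noise of 0.05 °C (the NETD class of research thermal
    cameras). Fiducial centres are ordered upper-left, upper-right,
    lower-left, lower-right to match the layout.
    """

    shape: tuple[int, int] = (240, 320)
    background_c: float = 33.0
    background_gradient: tuple[float, float] = (0.0, 0.0)  # °C per px (row, col)
    fiducial_centers: tuple[tuple[float, float], ...] = field(
        default_factory=_default_fiducials
    )
    fiducial_radius_px: float = 2.5
    fiducial_temp_c: float = 29.5
    layout: FiducialLayout = field(default_factory=FiducialLayout)
    hotspots: tuple[HotspotSpec, ...] = field(default_factory=_default_hotspots)
    noise_sd_c: float = 0.05
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)
    n_frames: int = 150
    frame_rate_hz: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if len(self.fiducial_centers) != 4:
            raise ValueError("exactly 4 fiducial centres are required")
        if self.noise_sd_c < 0:
            raise ValueError("noise sd must be >= 0")
        if self.n_frames < 1:
            raise ValueError("frame count must be >= 1")
        if self.shape[0] <= 0 or self.shape[1] <= 0:
            raise ValueError("image dims must be positive")


@dataclass
class SceneGroundTruth:
    """What the generator knows exactly about the scene it rendered."""

    hotspot_masks: list[dict[str, np.ndarray]]  # per frame, keyed by side
    transform: PlanarTransform  # frame-0 pixel -> cm homography
    fiducial_centers_px: list[np.ndarray]  # per frame, (4, 2) (row, col)
    plateau_area_px: dict[str, float]  # analytic ellipse area per side
    plateau_temp_c: dict[str, float]  # background + plateau elevation

    def plateau_area_m2(self, side: str, frame: int = 0) -> float:
        """Metric area of the rendered plateau mask (the discrete scene's
        exact ground truth, which differs from the analytic ellipse area by
        boundary discretization)."""
        from .calibration import roi_area_m2

        return roi_area_m2(self.hotspot_masks[frame][side], self.transform)


def _render_frame(
    spec: SceneSpec, frame_idx: int
) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray]:
    h, w = spec.shape
    off_r = spec.drift_px_per_frame[0] * frame_idx
    off_c = spec.drift_px_per_frame[1] * frame_idx
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    gr, gc = spec.background_gradient
    values = spec.background_c + gr * (rr - off_r) + gc * (cc - off_c)

    masks: dict[str, np.ndarray] = {}
    for hs in spec.hotspots:
        r0 = hs.center[0] + off_r
        c0 = hs.center[1] + off_c
        a, b = hs.semi_axes
        d = np.sqrt(((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2)
        plateau = d <= 1.0
        # clipped sigmoid: exact plateau inside, tail of the sigmoid outside
        # (distance past the boundary measured in pixels)
        e_px = np.maximum(d - 1.0, 0.0) * min(a, b)
        with np.errstate(over="ignore"):
            tail = hs.delta_t_c / (1.0 + np.exp(e_px / hs.edge_width_px))
        profile = np.where(plateau, hs.delta_t_c, tail)
        values = values + profile
        masks[hs.side] = plateau

    centers = np.asarray(spec.fiducial_centers, dtype=float) + [off_r, off_c]
    for fr, fc in centers:
        disk = (rr - fr) ** 2 + (cc - fc) ** 2 <= spec.fiducial_radius_px**2
        for side, m in masks.items():
            if np.any(disk & m):
                raise ValueError(
                    f"hotspot '{side}' overlaps a fiducial disk at frame "
                    f"{frame_idx} — this would confound calibration"
                )
        values[disk] = spec.fiducial_temp_c
    return values, masks, centers


def generate_sequence(spec: SceneSpec) -> tuple[ThermalSequence, SceneGroundTruth]:
    """Render a sequence and its exact ground truth.

    Deterministic for a given ``spec.seed``. Noise is added after scene
    composition, so with ``noise_sd_c = 0`` every non-fiducial, non-hotspot
    pixel equals the (possibly graded) background exactly and the plateau
    interior equals background + elevation exactly.
    """
    rng = np.random.default_rng(spec.seed)
    frames: list[ThermalFrame] = []
    gt_masks: list[dict[str, np.ndarray]] = []
    gt_centers: list[np.ndarray] = []
    for i in range(spec.n_frames):
        values, masks, centers = _render_frame(spec, i)
        if spec.noise_sd_c > 0:
            values = values + rng.normal(0.0, spec.noise_sd_c, size=values.shape)
        frames.append(ThermalFrame(values, i))
        gt_masks.append(masks)
        gt_centers.append(centers)

    transform = estimate_transform(gt_centers[0], spec.layout)
    plateau_area = {
        hs.side: float(np.pi * hs.semi_axes[0] * hs.semi_axes[1])
        for hs in spec.hotspots
    }
    plateau_temp = {hs.side: spec.background_c + hs.delta_t_c for hs in spec.hotspots}
    seq = ThermalSequence(
        frames,
        frame_rate_hz=spec.frame_rate_hz,
        duration_s=spec.n_frames / spec.frame_rate_hz,
    )
    truth = SceneGroundTruth(
        hotspot_masks=gt_masks,
        transform=transform,
        fiducial_centers_px=gt_centers,
        plateau_area_px=plateau_area,
        plateau_temp_c=plateau_temp,
    )
    return seq, truth


def generate_cohort(
    n_subjects: int = 24,
    responder_fraction: float = 0.25,
    baseline_mean_w: float = 3.0,
    baseline_sd_w: float = 0.5,
    nonresponder_pct: tuple[float, float] = (15.0, 8.0),
    responder_pct: tuple[float, float] = (45.0, 10.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject baseline and cold-stimulated total heat outputs.

    Emulates the 24-subject cold-challenge design: a quarter of subjects are
    high-BAT responders whose percent change in total heat output is drawn
    from a higher (mean, sd) normal distribution than the non-responders.
    The responder count is the rounded fraction of n (6 of 24 at the
    defaults), assigned to subjects at random. Columns: ``subject_id``,
    ``is_responder`` (ground truth), ``baseline_w``, ``stimulated_w``,
    ``pct_change``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not (0.0 <= responder_fraction <= 1.0):
        raise ValueError("responder_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_resp = int(round(responder_fraction * n_subjects))
    labels = np.zeros(n_subjects, dtype=bool)
    labels[rng.choice(n_subjects, size=n_resp, replace=False)] = True

    baseline = rng.normal(baseline_mean_w, baseline_sd_w, size=n_subjects)
    baseline = np.clip(baseline, 0.1, None)  # radiated power is positive
    pct = np.where(
        labels,
        rng.normal(responder_pct[0], responder_pct[1], size=n_subjects),
        rng.normal(nonresponder_pct[0], nonresponder_pct[1], size=n_subjects),
    )
    stimulated = baseline * (1.0 + pct / 100.0)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:02d}" for i in range(n_subjects)],
            "is_responder": labels,
            "baseline_w": baseline,
            "stimulated_w": stimulated,
            "pct_change": pct,
        }
    )
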