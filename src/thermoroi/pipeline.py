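"""End-to-end measurement: sequence -> calibrated ROI heat output.

Ties the stages together the way the acquisition protocol does: calibrate
once per sequence from the fiducial disks of a designated frame (optionally
per frame), mask the cool fiducial pixels out of the search windows, run
seeded region growing on every frame, average the per-frame ROI statistics
over the sequence, and apply the Stefan-Boltzmann law to the averaged area
and temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    DEFAULT_FIDUCIAL_BAND_C,
    FiducialLayout,
    PlanarTransform,
    detect_fiducials,
    estimate_transform,
    fiducial_exclusion_mask,
    roi_area_m2,
)
from .io import ThermalSequence
from .quantification import (
    PhysConstants,
    RoiMeasurement,
    celsius_to_kelvin,
    heat_output,
)
from .segmentation import (
    SearchWindow,
    SegmentationParams,
    SequenceSegmentation,
    segment_sequence,
)

__all__ = ["SideResult", "measure_sequence"]


@dataclass
class SideResult:
    """Measurement and heat output of one body side's ROI."""

    measurement: RoiMeasurement
    watts: float  # law applied to sequence-averaged (A, T) — protocol order
    watts_per_frame_mean: float  # mean of per-frame powers (diagnostic)
    segmentation: SequenceSegmentation


def measure_sequence(
    seq: ThermalSequence,
    windows: dict[str, SearchWindow],
    params: SegmentationParams,
    layout: FiducialLayout | None = None,
    constants: PhysConstants = PhysConstants(),
    fiducial_band: tuple[float, float] = DEFAULT_FIDUCIAL_BAND_C,
    calibration_frame: int = 0,
    per_frame_calibration: bool = False,
    transform: PlanarTransform | None = None,
) -> dict[str, SideResult]:
    """Measure ROI heat output per side for one sequence.

    A pre-computed ``transform`` skips fiducial detection (useful when the
    scene has no rendered disks). Otherwise the four disks are detected on
    ``calibration_frame`` and the exact four-point homography estimated; with
    ``per_frame_calibration`` the transform is re-estimated on every frame so
    pose drift changes pixel counts but not metric areas.
    """
    if layout is None:
        layout = FiducialLayout()
    transforms: list[PlanarTransform]
    if transform is not None:
        transforms = [transform] * len(seq)
        exclude = None
    else:
        if per_frame_calibration:
            transforms = [
                estimate_transform(detect_fiducials(f, band=fiducial_band), layout)
                for f in seq
            ]
        else:
            centers = detect_fiducials(seq[calibration_frame], band=fiducial_band)
            transforms = [estimate_transform(centers, layout)] * len(seq)
        exclude = [fiducial_exclusion_mask(f, band=fiducial_band) for f in seq]

    results: dict[str, SideResult] = {}
    for side, window in windows.items():
        segres = segment_sequence(seq, window, params, exclude=exclude)
        areas, temps = [], []
        for i, fs in enumerate(segres.frames):
            if fs is None:
                continue
            areas.append(roi_area_m2(fs.mask, transforms[i]))
            temps.append(fs.mean_temperature_c)
        mean_area = float(np.mean(areas))
        mean_temp_k = celsius_to_kelvin(float(np.mean(temps)))
        m = RoiMeasurement(
            side=side,
            area_m2=mean_area,
            temperature_k=mean_temp_k,
            mean_pixel_count=segres.mean_pixel_count,
            n_frames=segres.n_frames_processed,
        )
        watts = heat_output(m, constants)
        per_frame = [
            heat_output(
                RoiMeasurement(
                    side=side,
                    area_m2=a,
                    temperature_k=celsius_to_kelvin(t),
                    validate=False,
                ),
                constants,
            )
            for a, t in zip(areas, temps)
        ]
        results[side] = SideResult(
            measurement=m,
            watts=watts,
            watts_per_frame_mean=float(np.mean(per_frame)),
            segmentation=segres,
        )
    return results
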