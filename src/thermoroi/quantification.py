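"""Radiated heat output of detected ROIs via the Stefan-Boltzmann law.

The sequence-averaged ROI area A (m²) and mean ROI temperature T (K) give the
radiated power

    W = epsilon * sigma * A * T**4

with skin emissivity epsilon = 0.98 and sigma = 5.676e-8 W m^-2 K^-4 (the
value used by the source protocol). Left and right supraclavicular outputs
are summed to a total; stimulation responses are expressed as deltas and
percent changes against baseline.

Because T**4 is nonlinear, applying the law to the sequence-averaged (A, T)
(the protocol's order, and the default here) differs slightly from averaging
per-frame powers; both are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UnitError

__all__ = [
    "PhysConstants",
    "RoiMeasurement",
    "HeatOutput",
    "celsius_to_kelvin",
    "heat_output",
    "total_heat",
    "percent_change_heat",
    "KELVIN_OFFSET",
    "PLAUSIBLE_SKIN_K",
]

KELVIN_OFFSET = 273.15

#: Plausible band for mean skin ROI temperatures in kelvin; a value far below
#: this almost certainly means °C were passed where K were expected.
PLAUSIBLE_SKIN_K = (300.0, 315.0)


@dataclass(frozen=True)
class PhysConstants:
    """Emissivity of human skin and the Stefan-Boltzmann constant."""

    emissivity: float = 0.98
    sigma_w_m2_k4: float = 5.676e-8

    def __post_init__(self):
        if not (0 < self.emissivity <= 1):
            raise ValueError("emissivity must be in (0, 1]")
        if self.sigma_w_m2_k4 <= 0:
            raise ValueError("sigma must be positive")


def celsius_to_kelvin(temp_c: float) -> float:
    return temp_c + KELVIN_OFFSET


@dataclass
class RoiMeasurement:
    """Sequence-averaged ROI measurement feeding the radiometric law.

    ``area_m2`` and ``temperature_k`` are means over the processed frames;
    ``validate`` guards against the classic °C-for-K unit slip by requiring
    the temperature to sit in a plausible physiological band.
    """

    side: str
    area_m2: float
    temperature_k: float
    mean_pixel_count: float = 0.0
    n_frames: int = 0
    validate: bool = True

    def __post_init__(self):
        if self.area_m2 < 0:
            raise ValueError("area must be >= 0")
        if self.temperature_k <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.validate:
            lo, hi = PLAUSIBLE_SKIN_K
            if not (lo <= self.temperature_k <= hi):
                raise UnitError(
                    f"temperature {self.temperature_k:.2f} K outside the "
                    f"plausible skin band {lo}-{hi} K — was a Celsius value "
                    "passed where kelvin was expected? (set validate=False "
                    "to override)"
                )


@dataclass
class HeatOutput:
    """Radiated power (W) for the left/right ROIs and their sum."""

    left_w: float | None = None
    right_w: float | None = None
    timepoint: str = ""
    condition: str = ""

    def __post_init__(self):
        for v in (self.left_w, self.right_w):
            if v is not None and v < 0:
                raise ValueError("heat output must be >= 0")

    @property
    def total_w(self) -> float | None:
        if self.left_w is None or self.right_w is None:
            return None
        return total_heat(self.left_w, self.right_w)


def heat_output(m: RoiMeasurement, constants: PhysConstants = PhysConstants()) -> float:
    """Radiated power in watts: epsilon * sigma * A * T^4."""
    return constants.emissivity * constants.sigma_w_m2_k4 * m.area_m2 * m.temperature_k**4


def total_heat(left_w: float, right_w: float) -> float:
    """Sum of left and right ROI heat outputs (both must be non-negative)."""
    if left_w < 0 or right_w < 0:
        raise ValueError("heat outputs must be non-negative")
    return left_w + right_w


def percent_change_heat(baseline_w: float, stimulated_w: float) -> float:
    """Percent change of heat output relative to baseline (baseline > 0)."""
    if baseline_w <= 0:
        raise ValueError("baseline heat output must be positive")
    return 100.0 * (stimulated_w - baseline_w) / baseline_w
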