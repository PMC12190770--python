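"""Light-exposure arithmetic: power → irradiance → dosage.

All internal quantities are SI (W, m², s); the boundary helpers accept
the µW / µm² / mm² / min units that light-exposure protocols mix.
Dosage is the time integral of irradiance, so it is bilinear:
dosage(kI, t) = k dosage(I, t) = dosage(I, kt).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ExposureSpec",
    "irradiance_from_power",
    "dosage",
    "roi_scan_irradiance",
    "exposure_table",
    "UM2_TO_M2",
    "MM2_TO_M2",
    "UW_TO_W",
]

UW_TO_W = 1e-6
MM2_TO_M2 = 1e-6
UM2_TO_M2 = 1e-12
MIN_TO_S = 60.0


@dataclass(frozen=True)
class ExposureSpec:
    """A light exposure: irradiance sustained for a duration."""

    irradiance_W_m2: float
    duration_s: float
    dwell_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.irradiance_W_m2 < 0 or self.duration_s < 0:
            raise ValueError("irradiance and duration must be non-negative")
        if not 0.0 <= self.dwell_fraction <= 1.0:
            raise ValueError("dwell_fraction must be in [0, 1]")

    @property
    def dosage_J_m2(self) -> float:
        return dosage(self.irradiance_W_m2 * self.dwell_fraction, self.duration_s)


def irradiance_from_power(
    power: float,
    area: float,
    power_unit: str = "W",
    area_unit: str = "m2",
) -> float:
    """Irradiance (W/m²) = measured power / detector (or ROI) area."""
    factors_p = {"W": 1.0, "mW": 1e-3, "uW": UW_TO_W}
    factors_a = {"m2": 1.0, "mm2": MM2_TO_M2, "um2": UM2_TO_M2}
    if power_unit not in factors_p:
        raise ValueError(f"unknown power unit {power_unit!r}")
    if area_unit not in factors_a:
        raise ValueError(f"unknown area unit {area_unit!r}")
    area_m2 = area * factors_a[area_unit]
    if area_m2 <= 0:
        raise ValueError("area must be > 0")
    return power * factors_p[power_unit] / area_m2


def dosage(irradiance_W_m2: float, duration: float, duration_unit: str = "s") -> float:
    """Dosage (J/m²) = irradiance × exposure duration."""
    if irradiance_W_m2 < 0 or duration < 0:
        raise ValueError("inputs must be non-negative")
    factors = {"s": 1.0, "min": MIN_TO_S}
    if duration_unit not in factors:
        raise ValueError(f"unknown duration unit {duration_unit!r}")
    return irradiance_W_m2 * duration * factors[duration_unit]


def roi_scan_irradiance(
    power: float,
    roi_area: float,
    dwell_fraction: float = 1.0,
    power_unit: str = "uW",
    area_unit: str = "um2",
) -> float:
    """Effective irradiance of a laser-scanned ROI.

    The scan repeatedly covers the ROI, so the time-averaged irradiance
    over the stimulation period is the measured sample-plane power over
    the ROI area, optionally down-weighted by a scan duty factor.
    """
    if not 0.0 <= dwell_fraction <= 1.0:
        raise ValueError("dwell_fraction must be in [0, 1]")
    return dwell_fraction * irradiance_from_power(power, roi_area, power_unit, area_unit)


def exposure_table(
    irradiances_W_m2,
    duration_min: float,
) -> pd.DataFrame:
    """Tabulate an irradiance ladder with the dosage each step delivers."""
    rows = [
        {
            "irradiance_W_m2": float(i),
            "duration_min": float(duration_min),
            "dosage_J_m2": dosage(float(i), duration_min, "min"),
        }
        for i in irradiances_W_m2
    ]
    return pd.DataFrame(rows)
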