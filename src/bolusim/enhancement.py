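"""Iodine concentration <-> CT attenuation conversion.

Over the clinically relevant range, CT enhancement is linear in iodine
concentration; the slope depends on tube voltage (lower kV sits closer to
the iodine k-edge, hence a larger HU per mg I/mL).  Attenuation is
enhancement plus the unenhanced background (baseline) of the tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import CalibrationError, ValidationError
from .pbpk_core import ConcentrationCurve
from .tdc_metrics import TimeDensityCurve


@dataclass(frozen=True)
class EnhancementCalibration:
    """HU-per-(mg I/mL) coefficients keyed by tube voltage, plus baseline HU."""

    hu_per_mg_ml: Mapping[int, float]
    baseline_hu: float = 50.0

    def __post_init__(self) -> None:
        for kv, coeff in self.hu_per_mg_ml.items():
            if not coeff > 0:
                raise ValidationError(f"hu_per_mg_ml[{kv}] must be positive, got {coeff}")
        if self.baseline_hu < 0:
            raise ValidationError(f"baseline_hu must be >= 0, got {self.baseline_hu}")

    def coefficient(self, kv: int) -> float:
        try:
            return self.hu_per_mg_ml[kv]
        except KeyError:
            raise CalibrationError(
                f"no calibration for {kv} kV; available: {sorted(self.hu_per_mg_ml)}"
            ) from None

    @classmethod
    def from_config(cls, cfg: Mapping) -> "EnhancementCalibration":
        block = cfg["calibration"]
        return cls(
            hu_per_mg_ml={int(k): float(v) for k, v in block["hu_per_mg_ml"].items()},
            baseline_hu=float(block["baseline_hu"]),
        )


def concentration_to_hu(
    curve: ConcentrationCurve,
    calib: EnhancementCalibration,
    kv: int,
    tap: str | None = None,
) -> TimeDensityCurve:
    """Convert a tap's concentration curve to an attenuation TDC.

    ``attenuation(t) = coefficient[kv] * concentration(t) + baseline`` —
    linear and origin-preserving in concentration.
    """
    k = calib.coefficient(kv)
    if tap is None:
        tap = next(iter(curve.concentration))
    conc = curve.concentration[tap]
    return TimeDensityCurve(
        time_s=np.asarray(curve.time_s, dtype=float).copy(),
        attenuation_hu=k * conc + calib.baseline_hu,
        label="simulated",
        baseline_hu=calib.baseline_hu,
    )


def hu_to_concentration(
    tdc: TimeDensityCurve, calib: EnhancementCalibration, kv: int
) -> np.ndarray:
    """Invert the linear conversion; exact round trip up to float rounding."""
    k = calib.coefficient(kv)
    baseline = tdc.baseline_hu if tdc.baseline_hu is not None else calib.baseline_hu
    return (np.asarray(tdc.attenuation_hu, dtype=float) - baseline) / k


def calibrate_from_pairs(
    concentrations_mg_ml: Sequence[float], enhancements_hu: Sequence[float]
) -> float:
    """Least-squares slope through the origin from (concentration, HU) pairs."""
    c = np.asarray(concentrations_mg_ml, dtype=float)
    h = np.asarray(enhancements_hu, dtype=float)
    if c.shape != h.shape or c.size < 2:
        raise ValidationError("need >= 2 matched (concentration, HU) pairs")
    denom = float(c @ c)
    if denom == 0:
        raise ValidationError("all concentrations are zero; slope undefined")
    return float(c @ h) / denom
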