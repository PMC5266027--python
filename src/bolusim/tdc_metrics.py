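"""Time-density curves and their clinical summary metrics.

A time-density curve (TDC) is CT attenuation (HU) at a region of interest
as a function of time.  Three metrics summarise it:

* **ME** (maximum enhancement): peak attenuation minus baseline, HU;
* **TTP** (time to peak): time of the (first) maximum;
* **MTT** (mean transit time): here the venous peak time minus the arterial
  peak time — an operational peak-lag definition, not deconvolution MTT.

Curves round-trip through a small commented CSV format: ``#``-prefixed
metadata lines (label, baseline) followed by a ``time_s,hu`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateCurveError, ParseError, ValidationError

AUTO_BASELINE_WINDOW_S = 5.0

_LABELS = ("arterial", "venous", "simulated")


@dataclass
class TimeDensityCurve:
    """Attenuation vs time with optional known baseline.

    ``time_s`` must be strictly increasing with at least 3 samples and may
    be non-uniform; ``baseline_hu`` is the unenhanced background if known,
    otherwise it is estimated from the pre-arrival window.
    """

    time_s: np.ndarray
    attenuation_hu: np.ndarray
    label: str = "arterial"
    baseline_hu: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.attenuation_hu = np.asarray(self.attenuation_hu, dtype=float)
        if self.label not in _LABELS:
            raise ValidationError(f"label must be one of {_LABELS}, got {self.label!r}")
        if self.time_s.ndim != 1 or self.time_s.shape != self.attenuation_hu.shape:
            raise ValidationError("time and attenuation must be matched 1-D arrays")
        if self.time_s.size < 3:
            raise ValidationError(f"need >= 3 samples, got {self.time_s.size}")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValidationError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.attenuation_hu)):
            raise ValidationError("attenuation contains non-finite values")


@dataclass
class TDCMetrics:
    """ME / TTP (and optionally MTT) extracted from one curve."""

    me_hu: float
    ttp_s: float
    peak_attenuation_hu: float
    baseline_used_hu: float
    mtt_s: float | None = None

    def to_dict(self) -> dict:
        return {
            "me_hu": self.me_hu,
            "ttp_s": self.ttp_s,
            "peak_attenuation_hu": self.peak_attenuation_hu,
            "baseline_hu": self.baseline_used_hu,
            "mtt_s": self.mtt_s,
        }


def extract_metrics(
    curve: TimeDensityCurve,
    baseline: float | str | None = None,
    auto_window_s: float = AUTO_BASELINE_WINDOW_S,
    parabolic_peak: bool = False,
) -> TDCMetrics:
    """Peak attenuation, time to peak, and maximum enhancement of a curve.

    Baseline resolution order: an explicit numeric ``baseline`` argument,
    then the curve's own ``baseline_hu``, then automatic estimation as the
    mean of the samples in the first ``auto_window_s`` seconds (the
    pre-arrival window under the usual scan-delay convention).  Peak ties
    break to the earliest time.  ``parabolic_peak`` refines peak height and
    time by fitting a parabola through the maximum and its neighbours
    (off by default; reported peak times are then grid times).
    """
    att = curve.attenuation_hu
    t = curve.time_s

    if isinstance(baseline, str) and baseline != "auto":
        raise ValidationError(f"baseline must be a number, None or 'auto', got {baseline!r}")
    if baseline is None or baseline == "auto":
        baseline_value = curve.baseline_hu
    else:
        baseline_value = float(baseline)
    if baseline_value is None:
        if np.ptp(att) == 0:
            raise DegenerateCurveError(
                "flat curve: cannot estimate a baseline automatically"
            )
        window = t <= t[0] + auto_window_s
        baseline_value = float(att[window].mean())

    idx = int(np.argmax(att))  # argmax returns the first maximum
    peak = float(att[idx])
    ttp = float(t[idx])
    if parabolic_peak and 0 < idx < t.size - 1:
        y0, y1, y2 = att[idx - 1], att[idx], att[idx + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            shift = 0.5 * (y0 - y2) / denom
            # local uniform spacing assumption around the peak
            h = 0.5 * (t[idx + 1] - t[idx - 1])
            ttp = float(t[idx] + shift * h)
            peak = float(y1 - 0.25 * (y0 - y2) * shift)

    if baseline_value > peak:
        warnings.warn(
            f"baseline {baseline_value} HU exceeds peak {peak} HU; ME is negative",
            stacklevel=2,
        )
    return TDCMetrics(
        me_hu=peak - baseline_value,
        ttp_s=ttp,
        peak_attenuation_hu=peak,
        baseline_used_hu=baseline_value,
    )


def compute_mtt(arterial_ttp_s: float, venous_ttp_s: float) -> float:
    """Mean transit time as venous peak time minus arterial peak time."""
    for name, value in (("arterial_ttp_s", arterial_ttp_s), ("venous_ttp_s", venous_ttp_s)):
        if value < 0:
            raise ValidationError(f"{name} must be >= 0, got {value}")
    mtt = venous_ttp_s - arterial_ttp_s
    if mtt < 0:
        warnings.warn(
            f"venous peak ({venous_ttp_s} s) precedes arterial peak "
            f"({arterial_ttp_s} s); MTT is negative",
            stacklevel=2,
        )
    return mtt


def write_tdc_csv(curve: TimeDensityCurve, path: str | Path) -> None:
    """Write a curve as ``# key: value`` metadata lines plus a time_s,hu table.

    Values are written with shortest round-trip float formatting, so
    ``read_tdc_csv(write_tdc_csv(c))`` reproduces the arrays exactly.
    """
    lines = [f"# label: {curve.label}"]
    if curve.baseline_hu is not None:
        lines.append(f"# baseline_hu: {float(curve.baseline_hu)!r}")
    lines.append("time_s,hu")
    for tv, av in zip(curve.time_s, curve.attenuation_hu):
        lines.append(f"{float(tv)!r},{float(av)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tdc_csv(path: str | Path) -> TimeDensityCurve:
    """Parse a TDC CSV written by :func:`write_tdc_csv` (or hand-made).

    Raises :class:`ParseError` with the offending line number for missing
    columns, non-numeric fields (including comma-decimal dialects) or a
    non-monotone time column.
    """
    label = "arterial"
    baseline: float | None = None
    times: list[float] = []
    values: list[float] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key, val = key.strip(), val.strip()
                    if key == "label":
                        label = val
                    elif key == "baseline_hu":
                        baseline = float(val)
                continue
            fields = [f.strip() for f in line.split(",")]
            if not header_seen:
                if fields[:2] != ["time_s", "hu"]:
                    raise ParseError(
                        f"line {lineno}: expected header 'time_s,hu', got {line!r}"
                    )
                header_seen = True
                continue
            if len(fields) != 2:
                raise ParseError(
                    f"line {lineno}: expected 2 comma-separated columns, got "
                    f"{len(fields)} — comma-decimal dialects are not supported, "
                    "use '.' as the decimal mark"
                )
            try:
                tv, av = float(fields[0]), float(fields[1])
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-numeric field in {line!r}; use '.' as "
                    "the decimal mark (comma-decimal dialect not supported)"
                ) from None
            if times and tv <= times[-1]:
                raise ParseError(
                    f"line {lineno}: time {tv} not strictly increasing "
                    f"(previous {times[-1]})"
                )
            times.append(tv)
            values.append(av)
    if not header_seen:
        raise ParseError("line 1: missing 'time_s,hu' header")
    if len(times) < 3:
        raise ParseError(f"need >= 3 samples, found {len(times)}")
    return TimeDensityCurve(
        time_s=np.array(times),
        attenuation_hu=np.array(values),
        label=label,
        baseline_hu=baseline,
    )
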