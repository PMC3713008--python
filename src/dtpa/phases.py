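"""Automatic segmentation of the bolus passage into four time intervals.

The reference-region concentration curve of a DSCE examination is split into

* **BLP** — baseline period, before the contrast agent arrives,
* **IFP** — inflow period, arrival to peak concentration,
* **OFP** — outflow period, peak to the first post-peak local minimum,
* **RPP** — reperfusion period, the remainder of the acquisition.

Boundary conventions (half-open at arrival, closed at peak and minimum) are
fixed so the four intervals always partition the time axis:
``BLP = [0, toa)``, ``IFP = [toa, t_peak]``, ``OFP = (t_peak, t_min]``,
``RPP = (t_min, t_end]``.

Detection runs on a moving-average smoothed curve: the baseline mean and
standard deviation are estimated from pre-peak samples below 10% of the
maximum, the time of arrival is the first index exceeding
``mean + k_sigma * sd`` for two consecutive samples, the peak is the global
maximum and the minimum the first interior local minimum after it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .normalization import ConcentrationCurve

logger = logging.getLogger(__name__)

INTERVALS = ("BLP", "IFP", "OFP", "RPP")


@dataclass
class BolusPhases:
    """Detected time indices bounding the four bolus-passage intervals."""

    toa: int
    t_peak: int
    t_min: int
    n_time: int
    t_first: int = 0

    def __post_init__(self) -> None:
        if not (self.t_first <= self.toa < self.t_peak < self.t_min <= self.t_end):
            raise ValueError(
                f"phase indices must satisfy t_first <= toa < t_peak < t_min <= t_end, "
                f"got toa={self.toa} t_peak={self.t_peak} t_min={self.t_min} "
                f"t_end={self.t_end}"
            )
        if self.toa == self.t_first:
            raise ValueError("baseline period would be empty (toa == t_first)")
        if self.t_min == self.t_end:
            # keep the reperfusion period non-empty by ceding the final sample
            logger.warning(
                "no interior post-peak local minimum; assigning the final time "
                "point to RPP and shortening OFP"
            )
            if self.t_min - 1 <= self.t_peak:
                raise ValueError("cannot keep every interval non-empty")
            self.t_min = self.t_end - 1

    @property
    def t_end(self) -> int:
        return self.n_time - 1

    def interval_of(self, t: int) -> str:
        """Interval containing time index ``t``."""
        if not self.t_first <= t <= self.t_end:
            raise ValueError(f"time index {t} out of range")
        if t < self.toa:
            return "BLP"
        if t <= self.t_peak:
            return "IFP"
        if t <= self.t_min:
            return "OFP"
        return "RPP"

    def interval_members(self, interval: str) -> np.ndarray:
        """Ordered time indices belonging to ``interval``."""
        if interval == "BLP":
            return np.arange(self.t_first, self.toa)
        if interval == "IFP":
            return np.arange(self.toa, self.t_peak + 1)
        if interval == "OFP":
            return np.arange(self.t_peak + 1, self.t_min + 1)
        if interval == "RPP":
            return np.arange(self.t_min + 1, self.t_end + 1)
        raise ValueError(f"unknown interval {interval!r}")


def moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with reflected ends; ``width`` must be odd."""
    if width % 2 == 0 or width < 1:
        raise ValueError("smoothing width must be odd and >= 1")
    if width == 1:
        return np.asarray(values, dtype=float)
    half = width // 2
    padded = np.pad(np.asarray(values, dtype=float), half, mode="reflect")
    kernel = np.full(width, 1.0 / width)
    return np.convolve(padded, kernel, mode="valid")


def detect_phases(
    curve: ConcentrationCurve | np.ndarray,
    k_sigma: float = 3.0,
    smooth_width: int = 3,
) -> BolusPhases:
    """Detect the four bolus-passage intervals on a reference-region curve."""
    values = curve.values if isinstance(curve, ConcentrationCurve) else np.asarray(curve, float)
    n = len(values)
    if n < 4:
        raise ValueError("curve must have at least 4 time points")
    smoothed = moving_average(values, smooth_width)

    t_peak = int(np.argmax(smoothed))
    vmax = smoothed[t_peak]
    baseline_idx = np.nonzero(smoothed[:t_peak] < 0.1 * vmax)[0]
    if t_peak == 0 or len(baseline_idx) == 0:
        raise ValueError("no bolus detected: no baseline samples before the peak")
    mu = smoothed[baseline_idx].mean()
    sigma = smoothed[baseline_idx].std()
    if sigma == 0 and vmax <= mu:
        raise ValueError("no bolus detected: flat curve")

    threshold = mu + k_sigma * sigma
    toa = None
    for i in range(t_peak):
        if smoothed[i] > threshold and (i + 1 > t_peak or smoothed[i + 1] > threshold):
            toa = i
            break
    if toa is None:
        raise ValueError("no bolus detected: arrival threshold never sustained before peak")
    if toa == 0:
        raise ValueError("no baseline period: arrival at the first sample")

    t_min = n - 1
    for i in range(t_peak + 1, n - 1):
        if smoothed[i] <= smoothed[i - 1] and smoothed[i] <= smoothed[i + 1]:
            t_min = i
            break
    return BolusPhases(toa=toa, t_peak=t_peak, t_min=t_min, n_time=n)


def interval_members(phases: BolusPhases, interval: str) -> np.ndarray:
    """Module-level alias for :meth:`BolusPhases.interval_members`."""
    return phases.interval_members(interval)
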