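"""Baseline estimation, peak detection and integration on a single trace.

The detector follows conventional single-wavelength UV integration: a
morphological-opening baseline, apex detection on the baseline-subtracted
trace, perpendicular-drop boundaries at valley minima between overlapping
peaks, and trapezoidal areas.  Analysis is restricted to a retention window
(default 28-75 min) that excludes the solvent front and early baseline
disturbance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from sklearn.base import BaseEstimator

from .simulate import Chromatogram

__all__ = [
    "Peak",
    "PeakError",
    "estimate_baseline",
    "robust_noise_sd",
    "PeakDetector",
    "detect_peaks",
    "peaks_to_frame",
]

DEFAULT_WINDOW = (28.0, 75.0)


class PeakError(ValueError):
    pass


@dataclass(frozen=True)
class Peak:
    """An integrated, retention-time-located chromatographic peak."""

    apex_rt: float
    start_rt: float
    end_rt: float
    height: float
    area: float
    peak_no: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.start_rt < self.apex_rt < self.end_rt:
            raise PeakError("peak bounds must bracket the apex")


def estimate_baseline(chrom: Chromatogram, window: float = 2.0) -> np.ndarray:
    """Baseline trace via grey opening followed by moving-average smoothing.

    ``window`` (minutes) must exceed the widest expected peak so the opening
    erases peaks while following slow drift.
    """
    if window <= 0:
        raise PeakError("window must be > 0")
    dt = chrom.sampling_interval
    size = int(round(window / dt))
    if size < 3:
        raise PeakError("window shorter than 3 sampling intervals")
    y = chrom.intensity
    opened = ndimage.grey_opening(y, size=size, mode="nearest")
    base = ndimage.uniform_filter1d(opened, size=size, mode="nearest")
    # Opening rides the noise floor (~1 sd below the noise mean); re-center
    # on the majority (peak-free) residual so peak-free regions average zero.
    return base + float(np.median(y - base))


def robust_noise_sd(y: np.ndarray) -> float:
    """Noise SD from the median absolute deviation of first differences."""
    d = np.diff(np.asarray(y, dtype=float))
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad / 0.6744897501960817 / np.sqrt(2.0))


class PeakDetector(BaseEstimator):
    """Detect and integrate peaks in an analysis window.

    Parameters
    ----------
    min_height : float, optional
        Apex threshold above baseline.  Default: 3 x the robust noise SD
        estimated from the baseline-subtracted window.
    min_area : float
        Discard integrated areas below this value (intensity * min); rejects
        noise spikes that clear the height threshold.
    min_width : float
        Minimum full width at half prominence (minutes); detector noise
        maxima are one to a few samples wide and fail this even when they
        clear the height threshold.
    window : (float, float)
        Analysis window in minutes; a peak belongs to it iff its apex does.
    baseline_window : float
        Minutes, passed to :func:`estimate_baseline`.
    """

    def __init__(
        self,
        min_height: Optional[float] = None,
        min_area: float = 1.0,
        window: tuple[float, float] = DEFAULT_WINDOW,
        baseline_window: float = 2.0,
        min_width: float = 0.03,
    ):
        self.min_height = min_height
        self.min_area = min_area
        self.window = window
        self.baseline_window = baseline_window
        self.min_width = min_width

    def transform(self, chrom: Chromatogram) -> list[Peak]:
        t = chrom.time
        y = chrom.intensity
        if t.size == 0 or np.any(~np.isfinite(y)):
            raise PeakError("empty or non-finite trace")
        lo, hi = self.window
        if t[0] > lo or t[-1] < hi:
            raise PeakError(
                f"chromatogram [{t[0]:g}, {t[-1]:g}] does not cover the "
                f"analysis window [{lo:g}, {hi:g}]"
            )
        corr = y - estimate_baseline(chrom, self.baseline_window)
        in_win = (t >= lo) & (t <= hi)

        height = self.min_height
        if height is None:
            height = 3.0 * robust_noise_sd(corr[in_win])
        height = max(height, 1e-12)

        dt = chrom.sampling_interval
        apexes, _ = signal.find_peaks(
            corr,
            height=height,
            prominence=height,
            width=max(self.min_width / dt, 1.0),
            rel_height=0.5,
        )
        apexes = apexes[in_win[apexes]]
        if apexes.size == 0:
            return []

        peaks = []
        for k, apex in enumerate(apexes):
            left_lim = apexes[k - 1] if k > 0 else None
            right_lim = apexes[k + 1] if k + 1 < apexes.size else None
            start = self._bound(corr, apex, -1, left_lim, height)
            end = self._bound(corr, apex, +1, right_lim, height)
            if end - start < 2:
                continue
            area = float(np.trapezoid(corr[start : end + 1], t[start : end + 1]))
            if area < self.min_area or area <= 0:
                continue
            peaks.append(
                Peak(
                    apex_rt=float(t[apex]),
                    start_rt=float(t[start]),
                    end_rt=float(t[end]),
                    height=float(corr[apex]),
                    area=area,
                )
            )
        return peaks

    @staticmethod
    def _bound(
        corr: np.ndarray,
        apex: int,
        step: int,
        neighbour: Optional[int],
        height: float,
    ) -> int:
        """Integration bound: valley minimum toward a neighbouring apex, or
        the point where the signal decays to the noise floor."""
        if neighbour is not None:
            lo, hi = (neighbour, apex) if step < 0 else (apex, neighbour)
            seg = corr[lo : hi + 1]
            return lo + int(np.argmin(seg))
        floor = max(1e-4 * corr[apex], 0.0)
        i = apex
        limit = corr.size - 1 if step > 0 else 0
        while i != limit:
            i += step
            if corr[i] <= floor or corr[i] <= 0:
                break
        return i


def detect_peaks(
    chrom: Chromatogram,
    min_height: Optional[float] = None,
    min_area: float = 1.0,
    analysis_window: tuple[float, float] = DEFAULT_WINDOW,
    baseline_window: float = 2.0,
    min_width: float = 0.03,
) -> list[Peak]:
    """Functional wrapper over :class:`PeakDetector`."""
    return PeakDetector(
        min_height, min_area, analysis_window, baseline_window, min_width
    ).transform(chrom)


def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    """Peak list as a DataFrame (CSV dialect of the pipeline)."""
    return pd.DataFrame(
        [
            {
                "peak_no": p.peak_no,
                "apex_rt": p.apex_rt,
                "start_rt": p.start_rt,
                "end_rt": p.end_rt,
                "height": p.height,
                "area": p.area,
            }
            for p in peaks
        ],
        columns=["peak_no", "apex_rt", "start_rt", "end_rt", "height", "area"],
    )
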