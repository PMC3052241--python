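"""Calibration, substitutive-standard quantification and content summaries.

Ten saponins are quantified on their own reference-standard curves; the
remaining seventeen are semi-quantified on the curve of the standard with
the closest molecular weight (justified by the near-inverse relation of
the 203 nm mass response to molecular weight).  Contents are expressed as
percent of the nominal total-saponin mass in the assay solution, so batch
totals need not sum to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .fingerprint import FingerprintTable
from .library import CalibrationCurve, SaponinRef

__all__ = [
    "QuantError",
    "QuantConfig",
    "CalibrationModel",
    "fit_calibration",
    "concentration_from_area",
    "content_percent",
    "map_common_peaks_to_library",
    "quantify_areas",
    "summarize",
    "FIVE_SAPONIN_PEAKS",
    "TEN_SAPONIN_PEAKS",
]

#: The five most abundant saponins (Rb1, Rg1, Rd, R1, Re) and the ten
#: peaks with their own reference standards, by fingerprint peak number.
FIVE_SAPONIN_PEAKS = (1, 2, 3, 9, 15)
TEN_SAPONIN_PEAKS = (1, 2, 3, 9, 11, 12, 13, 15, 23, 24)


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class QuantConfig:
    nominal_total: float = 50.0   # mg/ml total saponins in the injection
    assay_total: float = 0.5      # mg/ml total saponins in the assay solution
    flag_below_lod: bool = True

    def __post_init__(self) -> None:
        if self.assay_total <= 0:
            raise QuantError("assay_total must be > 0")


class CalibrationModel(BaseEstimator, RegressorMixin):
    """Ordinary-least-squares linear response model ``area = a * conc + b``.

    Fitted attributes: ``slope_``, ``intercept_``, ``r_squared_``.
    ``predict`` maps concentration to area; ``inverse`` maps area back to
    concentration.
    """

    def fit(self, conc, area) -> "CalibrationModel":
        x = np.asarray(conc, dtype=float).ravel()
        y = np.asarray(area, dtype=float).ravel()
        if x.size != y.size or np.unique(x).size < 3:
            raise QuantError("need >= 3 distinct concentrations")
        res = stats.linregress(x, y)
        if res.slope <= 0:
            raise QuantError("calibration slope must be positive")
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.stderr_ = float(res.stderr)
        return self

    def predict(self, conc):
        return self.slope_ * np.asarray(conc, dtype=float) + self.intercept_

    def inverse(self, area):
        return (np.asarray(area, dtype=float) - self.intercept_) / self.slope_

    def to_curve(
        self,
        curve_id: str = "fitted",
        source_standard: str = "",
        **kwargs,
    ) -> CalibrationCurve:
        return CalibrationCurve(
            curve_id=curve_id,
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            source_standard=source_standard,
            **kwargs,
        )


def fit_calibration(
    points: Sequence[tuple[float, float]],
    curve_id: str = "fitted",
    source_standard: str = "",
) -> CalibrationCurve:
    """Fit a calibration line to (concentration ug/ml, area) points."""
    conc, area = zip(*points)
    model = CalibrationModel().fit(conc, area)
    return model.to_curve(curve_id=curve_id, source_standard=source_standard)


def concentration_from_area(
    area: float, curve: CalibrationCurve
) -> tuple[float, bool]:
    """Invert the calibration line; negative estimates clip to zero.

    Returns ``(concentration ug/ml, in_range)``; ``in_range`` is False when
    the curve has no printed linear range or the estimate falls outside it.
    """
    conc = curve.concentration(area)
    in_range = False
    if curve.linear_range is not None:
        lo, hi = curve.linear_range
        in_range = lo <= conc <= hi
    if conc < 0:
        return 0.0, False
    return float(conc), bool(in_range)


def content_percent(conc: float, config: QuantConfig = QuantConfig()) -> float:
    """Percent of the nominal total-saponin mass in the assay solution."""
    if conc < 0:
        raise QuantError("concentration must be >= 0")
    return 100.0 * conc / (config.assay_total * 1000.0)


def map_common_peaks_to_library(
    fp: FingerprintTable,
    library: Sequence[SaponinRef],
    rt_tolerance: float = 0.5,
) -> dict[int, int]:
    """Map common-peak numbers to library peak numbers by retention time.

    Accepts a shared rigid offset between the run and the library method:
    the median RT difference of nearest pairs is removed before matching.
    """
    med = fp.median_rt
    lib = sorted(library, key=lambda s: s.retention_time)
    lib_rt = np.array([s.retention_time for s in lib])
    offs = [float(m - lib_rt[np.argmin(np.abs(lib_rt - m))]) for m in med]
    offset = float(np.median(offs)) if offs else 0.0
    mapping: dict[int, int] = {}
    used: set[int] = set()
    order = sorted(
        ((abs(m - offset - lib_rt[j]), cp, j) for cp, m in med.items() for j in range(len(lib))),
    )
    for d, cp, j in order:
        if d > rt_tolerance or cp in mapping or j in used:
            continue
        mapping[cp] = lib[j].peak_no
        used.add(j)
    return mapping


def quantify_areas(
    fp: FingerprintTable,
    library: Sequence[SaponinRef],
    curves: Sequence[CalibrationCurve],
    config: QuantConfig = QuantConfig(),
    mapping: Optional[dict[int, int]] = None,
) -> pd.DataFrame:
    """Per batch x peak concentrations and contents from matched areas.

    Returns a long DataFrame with columns ``batch, peak_no, name, area,
    curve_id, concentration, content_percent, mode, in_range, below_lod``.
    ``mode`` is ``quantified`` for the ten peaks with their own standard
    and ``semi-quantified`` otherwise.
    """
    by_no = {s.peak_no: s for s in library}
    curve_by_id = {c.curve_id: c for c in curves}
    if mapping is None:
        mapping = map_common_peaks_to_library(fp, library)
    rows = []
    for cp in fp.area.index:
        if cp not in mapping:
            continue
        sap = by_no[mapping[cp]]
        curve = curve_by_id[sap.curve_id]
        for batch in fp.batches:
            area = float(fp.area.loc[cp, batch])
            conc, in_range = concentration_from_area(area, curve)
            below_lod = (
                config.flag_below_lod and curve.lod is not None and conc < curve.lod
            )
            rows.append(
                {
                    "batch": batch,
                    "peak_no": sap.peak_no,
                    "name": sap.name,
                    "area": area,
                    "curve_id": curve.curve_id,
                    "concentration": conc,
                    "content_percent": content_percent(conc, config),
                    "mode": "quantified" if sap.has_standard else "semi-quantified",
                    "in_range": in_range,
                    "below_lod": below_lod,
                }
            )
    return pd.DataFrame(rows)


def _content_matrix(report: pd.DataFrame) -> pd.DataFrame:
    return report.pivot(index="peak_no", columns="batch", values="content_percent")


def summarize(contents: pd.DataFrame) -> dict:
    """Headline statistics of a peaks x batches content (%) matrix.

    Expects rows indexed by the 27 peak numbers, one column per batch.
    Returns per-peak ranges across batches, and per-batch sums over the
    five major saponins and the ten standard-bearing saponins with their
    extremes.
    """
    if {"batch", "peak_no", "content_percent"}.issubset(getattr(contents, "columns", [])):
        contents = _content_matrix(contents)
    expected = set(range(1, 28))
    missing_rows = sorted(expected - set(contents.index))
    if missing_rows:
        raise QuantError(f"content matrix is missing peaks {missing_rows}")
    gaps = contents.isna()
    if gaps.to_numpy().any():
        where = [
            f"peak {p} / batch {b}"
            for p, row in gaps.iterrows()
            for b, bad in row.items()
            if bad
        ]
        raise QuantError("content matrix has missing cells: " + ", ".join(where))

    five = contents.loc[list(FIVE_SAPONIN_PEAKS)].sum(axis=0)
    ten = contents.loc[list(TEN_SAPONIN_PEAKS)].sum(axis=0)
    total = contents.sum(axis=0)
    return {
        "per_peak_min": contents.min(axis=1).to_dict(),
        "per_peak_max": contents.max(axis=1).to_dict(),
        "five_saponin_sum": five.round(10).to_dict(),
        "ten_saponin_sum": ten.round(10).to_dict(),
        "five_saponin_range": (float(five.min()), float(five.max())),
        "ten_saponin_range": (float(ten.min()), float(ten.max())),
        "total": total.round(10).to_dict(),
    }
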