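"""Reference knowledge for the 27 characteristic saponins of the preparation.

The packaged resource carries, for each characteristic peak of the
fingerprint, the saponin identity, its nominal deprotonated mass [M-H]-,
the glycan-loss composition observed in negative-mode ESI-MS^n, the
retention time on the reference method, and the linear calibration curve
(own reference standard, or the substitutive standard of closest molecular
weight) used for quantification.  All masses are nominal (integer Da);
published tables round inconsistently by up to 1 Da, which downstream
matching absorbs with a +/-2 Da tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "RESIDUE_MASSES",
    "SaponinRef",
    "CalibrationCurve",
    "LibraryError",
    "load_library",
    "load_content_table",
    "assign_curve",
    "slope_mw_correlation",
]

#: Nominal residue masses (Da) of the neutral losses seen in MS^n ladders:
#: hexose (glucose), deoxyhexose (rhamnose), pentose (xylose/arabinose),
#: the C5H10 side-chain loss of dehydrated dammaranes, and water.
RESIDUE_MASSES: dict[str, int] = {
    "Hex": 162,
    "dHex": 146,
    "Pen": 132,
    "C5H10": 68,
    "H2O": 18,
}


class LibraryError(ValueError):
    """Raised when the packaged resource is malformed or inconsistent."""


@dataclass(frozen=True)
class CalibrationCurve:
    """A linear UV response model ``area = slope * conc + intercept``.

    ``source_mw`` / ``source_aglycone`` describe the reference standard the
    curve was fitted on and drive substitutive-standard assignment;
    ``surrogate_rank`` breaks exact ties between isobaric standards.
    """

    curve_id: str
    slope: float
    intercept: float
    source_standard: str
    source_mw: Optional[float] = None
    source_aglycone: Optional[float] = None
    linear_range: Optional[tuple[float, float]] = None
    r_squared: Optional[float] = None
    lod: Optional[float] = None
    surrogate_rank: int = 0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise LibraryError(f"curve {self.curve_id!r}: slope must be > 0")
        if self.linear_range is not None:
            lo, hi = self.linear_range
            if not lo < hi:
                raise LibraryError(f"curve {self.curve_id!r}: bad linear range")

    def area(self, conc: float) -> float:
        """Forward response: peak area at concentration ``conc`` (ug/ml)."""
        return self.slope * conc + self.intercept

    def concentration(self, area: float) -> float:
        """Invert the response; may be negative for areas below intercept."""
        return (area - self.intercept) / self.slope


@dataclass(frozen=True)
class SaponinRef:
    """One characteristic saponin peak of the fingerprint."""

    peak_no: int
    name: str
    deprotonated_mass: float
    retention_time: float
    glycan_losses: tuple[str, ...]
    curve_id: str
    mw: float
    aglycone_mass: Optional[float] = None
    has_standard: bool = False
    printed_fragments: tuple[float, ...] = field(default_factory=tuple)

    @property
    def loss_ladder(self) -> tuple[float, ...]:
        """Prefix-sum fragment ladder implied by the stored loss order."""
        out, m = [], self.deprotonated_mass
        for label in self.glycan_losses:
            m -= RESIDUE_MASSES[label]
            out.append(m)
        return tuple(out)


def _data_text(name: str) -> str:
    return resources.files("saponinfp.data").joinpath(name).read_text()


def load_library() -> tuple[list[SaponinRef], list[CalibrationCurve]]:
    """Load the packaged 27-saponin library and its ten calibration curves."""
    raw = json.loads(_data_text("saponin_library.json"))
    curves = []
    for rec in raw["curves"]:
        try:
            curves.append(
                CalibrationCurve(
                    curve_id=rec["curve_id"],
                    slope=rec["slope"],
                    intercept=rec["intercept"],
                    source_standard=rec["source_standard"],
                    source_mw=rec.get("source_mw"),
                    source_aglycone=rec.get("source_aglycone"),
                    linear_range=tuple(rec["linear_range"]) if rec.get("linear_range") else None,
                    r_squared=rec.get("r_squared"),
                    lod=rec.get("lod"),
                    surrogate_rank=rec.get("surrogate_rank", 0),
                )
            )
        except (KeyError, TypeError) as exc:
            raise LibraryError(f"malformed curve record {rec!r}") from exc
    curve_ids = {c.curve_id for c in curves}
    saponins = []
    for rec in raw["saponins"]:
        try:
            sap = SaponinRef(
                peak_no=rec["peak_no"],
                name=rec["name"],
                deprotonated_mass=rec["deprotonated_mass"],
                retention_time=rec["retention_time"],
                glycan_losses=tuple(rec["glycan_losses"]),
                aglycone_mass=rec.get("aglycone_mass"),
                has_standard=rec["has_standard"],
                curve_id=rec["curve_id"],
                mw=rec["mw"],
                printed_fragments=tuple(rec.get("printed_fragments", ())),
            )
        except (KeyError, TypeError) as exc:
            raise LibraryError(f"malformed saponin record {rec!r}") from exc
        if sap.curve_id not in curve_ids:
            raise LibraryError(
                f"peak {sap.peak_no} references unknown curve {sap.curve_id!r}"
            )
        unknown = set(sap.glycan_losses) - set(RESIDUE_MASSES)
        if unknown:
            raise LibraryError(f"peak {sap.peak_no}: unknown residues {unknown}")
        saponins.append(sap)
    saponins.sort(key=lambda s: s.peak_no)
    return saponins, curves


def load_content_table():
    """Published batches x peaks content matrix (%), as a pandas DataFrame.

    Rows are peak numbers 1..27, columns the ten production batches.
    """
    import pandas as pd

    raw = json.loads(_data_text("content_table.json"))
    df = pd.DataFrame(
        {int(k): v for k, v in raw["contents"].items()}, index=raw["batches"]
    ).T
    df = df.sort_index()
    df.index.name = "peak_no"
    return df


def assign_curve(
    mw: float,
    curves: Sequence[CalibrationCurve],
    aglycone_mass: Optional[float] = None,
) -> str:
    """Pick the substitutive calibration curve for an analyte of mass ``mw``.

    The curve whose reference standard is nearest in molecular weight wins,
    exploiting the approximately inverse MW dependence of the 203 nm response.
    Ties are broken by matching aglycone class when known, then toward the
    lower-MW standard, then by the packaged surrogate preference among
    isobaric standards.
    """
    if not curves:
        raise LibraryError("no calibration curves supplied")

    def key(c: CalibrationCurve):
        if c.source_mw is None:
            raise LibraryError(f"curve {c.curve_id!r} lacks a source MW")
        mismatch = 1
        if aglycone_mass is not None and c.source_aglycone == aglycone_mass:
            mismatch = 0
        return (abs(c.source_mw - mw), mismatch, c.source_mw, c.surrogate_rank)

    return min(curves, key=key).curve_id


def slope_mw_correlation(curves: Sequence[CalibrationCurve]) -> float:
    """Pearson correlation between standard MW and calibration slope.

    For the packaged curves this is strongly negative: at 203 nm the molar
    response is roughly constant across the dammarane glycosides, so the
    mass response falls as sugars are added.
    """
    pts = [(c.source_mw, c.slope) for c in curves if c.source_mw is not None]
    if len({mw for mw, _ in pts}) < 3:
        raise LibraryError("need >= 3 curves with distinct source MW")
    mw, slope = np.asarray(pts, dtype=float).T
    return float(np.corrcoef(mw, slope)[0, 1])
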