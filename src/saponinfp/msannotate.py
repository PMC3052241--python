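"""Neutral-loss annotation of negative-mode ESI-MS^n spectra.

Triterpene glycosides fragment by successive elimination of sugar residues
from the deprotonated molecular ion, so a spectrum is explained by a ladder:
an ordered sequence of residue losses whose prefix sums, subtracted from
the precursor, land on observed fragments.  Candidate identities are
library entries whose precursor mass matches and whose glycan composition
contains the best ladder; isobaric candidates (epimers, positional isomers)
are ranked by retention-time proximity when a retention time is supplied.

All arithmetic is on nominal (integer) masses with a +/-2 Da default
tolerance absorbing rounding inconsistencies of printed values.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .library import RESIDUE_MASSES, SaponinRef
from .peaks import Peak

__all__ = [
    "MSnSpectrum",
    "ExplainedFragment",
    "LossAnnotation",
    "MatchCandidate",
    "explain_fragments",
    "match_library",
    "annotate_run",
]


@dataclass(frozen=True)
class MSnSpectrum:
    """Precursor [M-H]- and fragment m/z list of one MS^n experiment."""

    precursor_mz: float
    fragments: tuple[float, ...] = ()
    level: int = 2

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        object.__setattr__(self, "fragments", tuple(float(f) for f in self.fragments))


@dataclass(frozen=True)
class ExplainedFragment:
    step: int          # 1-based index into the loss sequence
    expected_mz: float
    observed_mz: float

    @property
    def delta(self) -> float:
        return self.observed_mz - self.expected_mz


@dataclass(frozen=True)
class LossAnnotation:
    loss_sequence: tuple[str, ...]
    explained: tuple[ExplainedFragment, ...] = field(default_factory=tuple)

    @property
    def n_explained(self) -> int:
        return len(self.explained)

    @property
    def total_abs_delta(self) -> float:
        return float(sum(abs(e.delta) for e in self.explained))

    @property
    def residue_multiset(self) -> Counter:
        """Loss composition ignoring adjunct water losses."""
        return Counter(l for l in self.loss_sequence if l != "H2O")

    def sort_key(self):
        # parsimony: among equally explanatory ladders prefer fewer losses
        return (
            -self.n_explained,
            self.total_abs_delta,
            len(self.loss_sequence),
            self.loss_sequence,
        )


def explain_fragments(
    spectrum: MSnSpectrum,
    residues: Mapping[str, float] = RESIDUE_MASSES,
    tolerance: float = 2.0,
    max_losses: int = 6,
    max_water: int = 1,
) -> list[LossAnnotation]:
    """Enumerate residue-loss ladders explaining the observed fragments.

    Depth-first search over loss sequences of length <= ``max_losses``
    (at most ``max_water`` water losses, to avoid combinatorial blow-up on
    an 18 Da step that is chemically an adjunct).  A sequence is reported
    when its final prefix sum matches an observed fragment within
    ``tolerance``; unmatched intermediate steps are allowed.  Annotations
    are ranked by (fragments explained desc, total |delta| asc, sequence).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if max_losses < 1:
        raise ValueError("max_losses must be >= 1")
    frags = np.asarray(sorted(spectrum.fragments), dtype=float)
    if frags.size == 0:
        return []
    fmin = float(frags[0])
    labels = sorted(residues)
    out: list[LossAnnotation] = []

    def match(expected: float) -> Optional[float]:
        i = int(np.searchsorted(frags, expected))
        hits = [
            (abs(frags[j] - expected), float(frags[j]))
            for j in (i - 1, i)
            if 0 <= j < frags.size and abs(frags[j] - expected) <= tolerance
        ]
        return min(hits)[1] if hits else None

    def dfs(seq: list[str], mass: float, expl: list[ExplainedFragment], n_water: int):
        if len(seq) >= max_losses or mass < fmin - tolerance:
            return
        for label in labels:
            if label == "H2O" and n_water >= max_water:
                continue
            m = mass - residues[label]
            if m <= 0:
                continue
            seq.append(label)
            obs = match(m)
            if obs is not None:
                hit = ExplainedFragment(len(seq), m, obs)
                out.append(LossAnnotation(tuple(seq), tuple(expl) + (hit,)))
                expl.append(hit)
                dfs(seq, m, expl, n_water + (label == "H2O"))
                expl.pop()
            else:
                dfs(seq, m, expl, n_water + (label == "H2O"))
            seq.pop()

    dfs([], float(spectrum.precursor_mz), [], 0)
    out.sort(key=LossAnnotation.sort_key)
    return out


@dataclass(frozen=True)
class MatchCandidate:
    saponin: SaponinRef
    mass_delta: float
    rt_delta: Optional[float] = None
    n_explained: int = 0


def match_library(
    spectrum: MSnSpectrum,
    annotations: Sequence[LossAnnotation],
    library: Sequence[SaponinRef],
    tolerance: float = 2.0,
    rt: Optional[float] = None,
) -> list[MatchCandidate]:
    """Rank library entries consistent with a spectrum and its best ladder.

    A candidate must match the precursor within ``tolerance`` and its
    glycan-loss multiset must contain the best annotation's residue
    multiset (water losses are adjunct and not required).  With a retention
    time, isobaric candidates are ordered by retention proximity; otherwise
    by mass agreement and peak number.
    """
    best = annotations[0] if annotations else None
    required = best.residue_multiset if best else Counter()
    n_explained = best.n_explained if best else 0
    cands = []
    for sap in library:
        dm = spectrum.precursor_mz - sap.deprotonated_mass
        if abs(dm) > tolerance:
            continue
        have = Counter(sap.glycan_losses)
        if any(have[k] < v for k, v in required.items()):
            continue
        cands.append(
            MatchCandidate(
                saponin=sap,
                mass_delta=float(dm),
                rt_delta=(rt - sap.retention_time) if rt is not None else None,
                n_explained=n_explained,
            )
        )
    if rt is not None:
        cands.sort(key=lambda c: (abs(c.rt_delta), c.saponin.peak_no))
    else:
        cands.sort(key=lambda c: (abs(c.mass_delta), c.saponin.peak_no))
    return cands


def annotate_run(
    peak_spectra: Sequence[tuple[Peak, Sequence[MSnSpectrum]]],
    library: Sequence[SaponinRef],
    residues: Mapping[str, float] = RESIDUE_MASSES,
    tolerance: float = 2.0,
    rt_window: float = 1.0,
) -> pd.DataFrame:
    """Identify a detected-peak table from per-peak MS^n spectra.

    Modes: ``reference-matched`` (top candidate has its own standard and
    elutes within ``rt_window`` minutes), ``tentative`` (mass and loss
    composition only), ``unknown`` (no spectrum or no candidate).
    """
    rows = []
    for peak, spectra in peak_spectra:
        rec = {
            "apex_rt": peak.apex_rt,
            "peak_no": None,
            "name": None,
            "mode": "unknown",
            "precursor": None,
            "losses": "",
            "score": 0,
        }
        spectra = list(spectra)
        if spectra:
            spec = spectra[0]
            rec["precursor"] = spec.precursor_mz
            anns = explain_fragments(spec, residues, tolerance)
            cands = match_library(spec, anns, library, tolerance, rt=peak.apex_rt)
            if cands:
                top = cands[0]
                rec["peak_no"] = top.saponin.peak_no
                rec["name"] = top.saponin.name
                rec["losses"] = "+".join(anns[0].loss_sequence) if anns else ""
                rec["score"] = top.n_explained
                close = abs(top.rt_delta) <= rt_window if top.rt_delta is not None else False
                if top.saponin.has_standard and close:
                    rec["mode"] = "reference-matched"
                else:
                    rec["mode"] = "tentative"
        rows.append(rec)
    return pd.DataFrame(
        rows, columns=["apex_rt", "peak_no", "name", "mode", "precursor", "losses", "score"]
    )
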