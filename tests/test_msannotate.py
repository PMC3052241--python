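"""Neutral-loss ladder enumeration and library identification."""

import itertools
from collections import Counter

import numpy as np
import pytest

from saponinfp import (
    RESIDUE_MASSES,
    MSnSpectrum,
    annotate_run,
    explain_fragments,
    match_library,
    simulate_msn,
)
from saponinfp.msannotate import LossAnnotation
from saponinfp.peaks import Peak


def brute_force_ladders(spectrum, residues, tolerance, max_losses, max_water=1):
    """Independent oracle: exhaustive enumeration over all loss sequences."""
    frags = sorted(spectrum.fragments)
    if not frags:
        return []

    def nearest(expected):
        hits = [(abs(f - expected), f) for f in frags if abs(f - expected) <= tolerance]
        return min(hits)[1] if hits else None

    out = []
    labels = sorted(residues)
    for n in range(1, max_losses + 1):
        for seq in itertools.product(labels, repeat=n):
            if sum(l == "H2O" for l in seq) > max_water:
                continue
            mass = spectrum.precursor_mz
            explained = []
            ok_prefix = True
            for k, label in enumerate(seq, start=1):
                mass -= residues[label]
                if mass <= 0:
                    ok_prefix = False
                    break
                obs = nearest(mass)
                if obs is not None:
                    explained.append((k, mass, obs))
            if not ok_prefix or not explained:
                continue
            if explained[-1][0] != len(seq):  # trailing unmatched losses
                continue
            out.append(
                (
                    -len(explained),
                    sum(abs(o - e) for _, e, o in explained),
                    len(seq),
                    seq,
                    tuple(explained),
                )
            )
    out.sort()
    return [(seq, expl) for *_, seq, expl in out]


@pytest.mark.parametrize(
    "precursor,fragments",
    [
        (1107, (945, 783, 621, 459)),
        (932, (799, 637, 475)),
        (783, (637, 621, 475)),
        (800, (637, 619, 475)),
        (619, (551,)),
    ],
)
@pytest.mark.parametrize("tolerance", [0.0, 2.0])
def test_explain_fragments_equals_brute_force(precursor, fragments, tolerance):
    spec = MSnSpectrum(precursor, fragments)
    got = explain_fragments(spec, RESIDUE_MASSES, tolerance, max_losses=4)
    want = brute_force_ladders(spec, RESIDUE_MASSES, tolerance, max_losses=4)
    assert [a.loss_sequence for a in got] == [seq for seq, _ in want]
    for ann, (_, expl) in zip(got, want):
        assert [(e.step, e.expected_mz, e.observed_mz) for e in ann.explained] == list(expl)


def test_explain_fragments_equals_brute_force_random_spectra():
    rng = np.random.default_rng(5)
    for _ in range(15):
        precursor = float(rng.integers(600, 1300))
        frags = tuple(
            float(f)
            for f in rng.choice(np.arange(400, int(precursor) - 50), size=5, replace=False)
        )
        spec = MSnSpectrum(precursor, frags)
        got = explain_fragments(spec, RESIDUE_MASSES, 2.0, max_losses=4)
        want = brute_force_ladders(spec, RESIDUE_MASSES, 2.0, max_losses=4)
        assert [a.loss_sequence for a in got] == [seq for seq, _ in want]


def test_best_ladders_for_printed_spectra():
    anns = explain_fragments(MSnSpectrum(1107, (945, 783, 621, 459)), tolerance=2.0)
    assert anns[0].loss_sequence == ("Hex", "Hex", "Hex", "Hex")
    assert anns[0].n_explained == 4
    anns = explain_fragments(MSnSpectrum(1209, (1077, 945, 783, 621)), tolerance=2.0)
    assert anns[0].loss_sequence[:2] == ("Pen", "Pen")
    assert explain_fragments(MSnSpectrum(1107, ())) == []


def test_tolerance_monotonicity():
    spec = MSnSpectrum(932, (799, 637, 475))
    prev: set = set()
    for tol in (0.0, 0.5, 1.0, 2.0, 3.0):
        anns = explain_fragments(spec, tolerance=tol, max_losses=4)
        explained = {e.observed_mz for a in anns for e in a.explained}
        assert prev.issubset(explained)
        prev = explained


def test_match_library_examples(library):
    saponins, _ = library
    spec = MSnSpectrum(932, (799, 637, 475))
    cands = match_library(spec, explain_fragments(spec), saponins)
    assert cands[0].saponin.name == "Notoginsenoside R1"

    spec = MSnSpectrum(619, (551,))
    cands = match_library(spec, explain_fragments(spec), saponins, rt=63.42)
    assert [c.saponin.name for c in cands] == ["Ginsenoside Rk3", "Ginsenoside Rh4"]

    assert match_library(MSnSpectrum(9999), [], saponins) == []


def test_simulated_round_trip_ranks_unique_entries_first(library):
    saponins, _ = library
    counts = Counter(s.deprotonated_mass for s in saponins)
    for s in saponins:
        if counts[s.deprotonated_mass] > 1:
            continue
        spec = simulate_msn(s)
        cands = match_library(spec, explain_fragments(spec, tolerance=2.0), saponins)
        assert cands and cands[0].saponin.peak_no == s.peak_no


def _stub(rt):
    return Peak(apex_rt=rt, start_rt=rt - 0.1, end_rt=rt + 0.1, height=1.0, area=1.0)


def test_annotate_run_recovers_all_27_assignments(library):
    saponins, _ = library
    entries = [(_stub(s.retention_time), [simulate_msn(s)]) for s in saponins]
    ids = annotate_run(entries, saponins)
    assert list(ids["peak_no"]) == [s.peak_no for s in saponins]
    assert list(ids["name"]) == [s.name for s in saponins]
    modes = ids["mode"].value_counts().to_dict()
    assert modes == {"tentative": 17, "reference-matched": 10}
    named = [n for n in ids["name"] if not n.startswith("unknown-")]
    assert len(named) == 23
    assert sorted(n for n in ids["name"] if n.startswith("unknown-")) == [
        "unknown-752", "unknown-752", "unknown-765", "unknown-765",
    ]


def test_annotate_run_no_spectrum_is_unknown(library):
    saponins, _ = library
    ids = annotate_run([(_stub(50.0), [])], saponins)
    assert ids.loc[0, "mode"] == "unknown"


def test_isobaric_752_pair_resolved_only_by_retention(library):
    saponins, _ = library
    p17 = next(s for s in saponins if s.peak_no == 17)
    p19 = next(s for s in saponins if s.peak_no == 19)
    spec = simulate_msn(p17)
    anns = explain_fragments(spec, tolerance=2.0)
    c17 = match_library(spec, anns, saponins, rt=p17.retention_time)
    c19 = match_library(spec, anns, saponins, rt=p19.retention_time)
    assert {c.saponin.peak_no for c in c17} == {c.saponin.peak_no for c in c19} == {17, 19}
    assert c17[0].saponin.peak_no == 17
    assert c19[0].saponin.peak_no == 19


def test_annotation_invariants():
    ann = LossAnnotation(("Hex", "H2O", "Pen"))
    assert ann.residue_multiset == Counter({"Hex": 1, "Pen": 1})
    with pytest.raises(ValueError):
        MSnSpectrum(-1.0)
    with pytest.raises(ValueError):
        explain_fragments(MSnSpectrum(500, (400,)), tolerance=-1.0)
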