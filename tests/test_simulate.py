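"""Synthetic chromatogram/MS^n generator: determinism, areas, gradient."""

import numpy as np
import pytest

from saponinfp import (
    Chromatogram,
    GeneratorConfig,
    gradient_percent_b,
    simulate_batch,
    simulate_msn,
)
from saponinfp.library import SaponinRef
from saponinfp.simulate import GeneratorError, emg_profile


@pytest.mark.parametrize(
    "t,expected",
    [
        (0.0, 19.0),
        (30.0, 21.2),
        (62.0, 55.0),
        (32.5, 23.6),   # linear midpoint of 21.2-26 over 30-35 min
        (75.0, 95.0),
        (80.0, 19.0),   # re-equilibration
    ],
)
def test_gradient_program(t, expected):
    assert gradient_percent_b(t) == pytest.approx(expected)


@pytest.mark.parametrize("t", [-0.1, 85.5])
def test_gradient_domain_error(t):
    with pytest.raises(GeneratorError):
        gradient_percent_b(t)


def test_same_seed_bit_identical(library):
    saponins, curves = library
    cfg = GeneratorConfig(seed=7)
    c1, t1 = simulate_batch(cfg, saponins, curves, 3)
    c2, t2 = simulate_batch(cfg, saponins, curves, 3)
    assert np.array_equal(c1.intensity, c2.intensity)
    assert t1.equals(t2)
    c3, _ = simulate_batch(cfg, saponins, curves, 4)
    assert not np.array_equal(c1.intensity, c3.intensity)


def test_zero_content_zero_noise_is_flat(library):
    saponins, curves = library
    cfg = GeneratorConfig(
        true_contents={}, noise_sd=0.0, baseline_amplitude=0.0, solvent_front=0.0
    )
    chrom, truth = simulate_batch(cfg, saponins, curves, 0)
    assert np.all(chrom.intensity == 0.0)
    assert truth.empty


def test_noiseless_trace_integrates_to_truth_area(library):
    saponins, curves = library
    cfg = GeneratorConfig(
        true_contents={9: 0.28},
        rt_jitter_sd=0.0, rt_jitter_peak_sd=0.0, area_cv=0.0,
        noise_sd=0.0, baseline_amplitude=0.0, solvent_front=0.0,
    )
    chrom, truth = simulate_batch(cfg, saponins, curves, 0)
    num = np.trapezoid(chrom.intensity, chrom.time)
    assert num == pytest.approx(float(truth.area.iloc[0]), rel=1e-3)


def test_emg_profile_area_and_gaussian_limit():
    t = np.arange(0.0, 75.0, 0.01)
    y = emg_profile(t, 100.0, 50.0, 0.04, 0.03)
    assert np.trapezoid(y, t) == pytest.approx(100.0, rel=1e-3)
    assert t[np.argmax(y)] == pytest.approx(50.0, abs=0.01)
    g = emg_profile(t, 100.0, 50.0, 0.04, 0.0)  # tau=0 degenerates to Gaussian
    from scipy import stats

    assert np.allclose(g, 100.0 * stats.norm.pdf(t, 50.0, 0.04))


def test_area_linearity_in_concentration(library):
    """Doubling a true concentration doubles (area - intercept) exactly."""
    saponins, curves = library
    rh1 = next(c for c in curves if c.curve_id == "rh1")
    base = dict(
        rt_jitter_sd=0.0, rt_jitter_peak_sd=0.0, area_cv=0.0,
        noise_sd=0.0, baseline_amplitude=0.0, solvent_front=0.0,
    )
    _, t1 = simulate_batch(GeneratorConfig(true_contents={12: 0.02}, **base),
                           saponins, curves, 0)
    _, t2 = simulate_batch(GeneratorConfig(true_contents={12: 0.04}, **base),
                           saponins, curves, 0)
    assert (t2.area.iloc[0] - rh1.intercept) == pytest.approx(
        2.0 * (t1.area.iloc[0] - rh1.intercept)
    )


def test_nonpositive_area_error_names_peak(library):
    saponins, curves = library
    cfg = GeneratorConfig(true_contents={5: 0.001}, on_nonpositive_area="error")
    with pytest.raises(GeneratorError, match="peak 5"):
        simulate_batch(cfg, saponins, curves, 0)


def test_nonpositive_area_clips_to_floor(library):
    saponins, curves = library
    cfg = GeneratorConfig(
        true_contents={5: 0.001}, area_cv=0.0, noise_sd=0.0,
        baseline_amplitude=0.0, solvent_front=0.0,
    )
    _, truth = simulate_batch(cfg, saponins, curves, 0)
    assert float(truth.area.iloc[0]) == pytest.approx(cfg.area_floor)


@pytest.mark.parametrize(
    "kwargs", [dict(rt_jitter_sd=-0.1), dict(area_cv=-1.0), dict(dilution_to=100.0)]
)
def test_config_validation(kwargs):
    with pytest.raises(GeneratorError):
        GeneratorConfig(**kwargs)


def test_chromatogram_csv_round_trip(tmp_path, library):
    saponins, curves = library
    chrom, _ = simulate_batch(GeneratorConfig(seed=2), saponins, curves, 0)
    path = tmp_path / "chrom.csv"
    chrom.to_csv(path)
    back = Chromatogram.from_csv(path)
    assert np.allclose(back.time, chrom.time)
    assert np.allclose(back.intensity, chrom.intensity)
    assert back.meta["batch_id"] == chrom.meta["batch_id"]


def test_simulate_msn_ladders(library):
    saponins, _ = library
    rb1 = next(s for s in saponins if s.name == "Ginsenoside Rb1")
    spec = simulate_msn(rb1)
    assert spec.precursor_mz == 1107
    assert set(spec.fragments) == {945, 783, 621, 459}
    re_ = next(s for s in saponins if s.name == "Ginsenoside Re")
    assert {783, 637}.issubset(set(simulate_msn(re_).fragments))
    bare = SaponinRef(
        peak_no=99, name="x", deprotonated_mass=500, retention_time=10.0,
        glycan_losses=(), curve_id="rb1", mw=500,
    )
    assert simulate_msn(bare).fragments == ()
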