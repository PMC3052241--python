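"""Synthetic multi-batch HPLC-UV chromatograms and ESI-MS^n spectra.

The generator emulates the statistical structure of a fingerprint study on
a total-saponin injection: 27 exponentially-modified-Gaussian (EMG) peaks
at the library retention times, whose noiseless integrated areas sit exactly
on the assigned calibration lines at realistic content levels; batch-to-batch
retention jitter (a shared per-batch shift plus small independent per-peak
scatter) and log-normal area variability; a broad solvent-front disturbance
over 0-28 min; slow baseline drift; and additive white detector noise.

Because areas are generated by inverting the calibration lines, the ground
truth table returned with every batch closes the loop for end-to-end
parameter-recovery tests.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .library import CalibrationCurve, SaponinRef, load_content_table

__all__ = [
    "GeneratorConfig",
    "Chromatogram",
    "GeneratorError",
    "gradient_percent_b",
    "default_true_contents",
    "simulate_batch",
    "simulate_run",
    "simulate_msn",
]


class GeneratorError(ValueError):
    pass


# Printed binary-gradient program of the reference method (min, %B).
_GRADIENT_NODES = [
    (0.0, 19.0),
    (30.0, 21.2),
    (35.0, 26.0),
    (40.0, 28.0),
    (50.0, 38.0),
    (60.0, 55.0),
    (65.0, 55.0),
    (70.0, 80.0),
    (75.0, 95.0),
]


def gradient_percent_b(t: float) -> float:
    """Mobile-phase %B of the elution program at time ``t`` (minutes).

    Piecewise linear between the printed program nodes; after 75 min the
    column re-equilibrates at the initial 19% B until the 85 min run end.
    """
    t = float(t)
    if not 0.0 <= t <= 85.0:
        raise GeneratorError(f"t={t} outside the 0-85 min run")
    if t > 75.0:
        return 19.0
    xs, ys = zip(*_GRADIENT_NODES)
    return float(np.interp(t, xs, ys))


@dataclass(frozen=True)
class Chromatogram:
    """A sampled single-wavelength UV trace on a uniform time grid."""

    time: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise GeneratorError("time and intensity must be matching 1-D arrays")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise GeneratorError("time grid must be strictly increasing and uniform")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", y)

    @property
    def sampling_interval(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_csv(self, path_or_buf) -> None:
        """Write a two-column CSV with ``#``-prefixed metadata header lines."""
        buf = io.StringIO()
        for key, val in self.meta.items():
            buf.write(f"# {key}: {val}\n")
        buf.write("time_min,intensity\n")
        pd.DataFrame({"time_min": self.time, "intensity": self.intensity}).to_csv(
            buf, index=False, header=False
        )
        text = buf.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path_or_buf) -> "Chromatogram":
        if hasattr(path_or_buf, "read"):
            lines = path_or_buf.read().splitlines()
        else:
            with open(path_or_buf) as fh:
                lines = fh.read().splitlines()
        meta = {}
        body = []
        for line in lines:
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
            elif line.strip():
                body.append(line)
        df = pd.read_csv(io.StringIO("\n".join(body)))
        return cls(df["time_min"].to_numpy(), df["intensity"].to_numpy(), meta)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic fingerprint experiment.

    ``true_contents`` maps peak number to the content fraction of the
    nominal total saponins (defaults to the per-peak means of the packaged
    batch content table).  Concentrations in the assay solution follow from
    ``dilution_to`` (mg/ml total saponins after dilution).  Retention
    jitter decomposes into a per-batch shift (``rt_jitter_sd``) shared by
    all peaks plus small independent per-peak scatter
    (``rt_jitter_peak_sd``), matching the strong across-peak correlation of
    retention drift on a single instrument.
    """

    true_contents: Optional[Mapping[int, float]] = None
    nominal_total: float = 50.0
    dilution_to: float = 0.5
    rt_jitter_sd: float = 0.05
    rt_jitter_peak_sd: float = 0.005
    area_cv: float = 0.05
    peak_width_sd: float = 0.04
    emg_tau: float = 0.03
    baseline_amplitude: float = 5.0
    noise_sd: float = 0.5
    solvent_front: float = 60.0
    n_batches: int = 10
    seed: int = 0
    t_start: float = 0.0
    t_end: float = 75.0
    sampling_interval: float = 0.01
    area_floor: float = 5.0
    on_nonpositive_area: str = "clip"

    def __post_init__(self) -> None:
        for name in (
            "rt_jitter_sd",
            "rt_jitter_peak_sd",
            "area_cv",
            "peak_width_sd",
            "emg_tau",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise GeneratorError(f"{name} must be >= 0")
        if self.dilution_to > self.nominal_total:
            raise GeneratorError("dilution_to must not exceed nominal_total")
        if self.peak_width_sd == 0:
            raise GeneratorError("peak_width_sd must be > 0")
        if not self.t_start < self.t_end:
            raise GeneratorError("empty time range")
        if self.on_nonpositive_area not in ("clip", "error"):
            raise GeneratorError("on_nonpositive_area must be 'clip' or 'error'")

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def default_true_contents() -> dict[int, float]:
    """Per-peak content fractions: means of the packaged batch table."""
    table = load_content_table()
    return {int(k): float(v) / 100.0 for k, v in table.mean(axis=1).items()}


@lru_cache(maxsize=32)
def _emg_mode_offset(sigma: float, tau: float) -> float:
    """Apex position of a unit EMG relative to its Gaussian center."""
    if tau <= 1e-9 * sigma:
        return 0.0
    dist = stats.exponnorm(tau / sigma, loc=0.0, scale=sigma)
    res = optimize.minimize_scalar(
        lambda x: -dist.pdf(x), bounds=(0.0, 3.0 * (sigma + tau)), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def emg_profile(
    t: np.ndarray, area: float, apex_rt: float, sigma: float, tau: float
) -> np.ndarray:
    """EMG peak with a given integrated ``area`` and apex at ``apex_rt``."""
    mu = apex_rt - _emg_mode_offset(sigma, tau)
    if tau <= 1e-9 * sigma:
        return area * stats.norm.pdf(t, loc=mu, scale=sigma)
    return area * stats.exponnorm.pdf(t, tau / sigma, loc=mu, scale=sigma)


def _solvent_front(t: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Broad low-frequency disturbances confined to the 0-28 min region."""
    centers = np.array([1.5, 4.0, 8.0, 12.0, 16.0])
    widths = np.array([0.8, 1.5, 2.0, 2.5, 2.5])
    rel = np.array([1.0, 0.8, 0.6, 0.5, 0.35]) * rng.uniform(0.7, 1.3, size=5)
    out = np.zeros_like(t)
    for c, w, a in zip(centers, widths, rel):
        out += amplitude * a * np.exp(-0.5 * ((t - c) / w) ** 2)
    return out


def _batch_rng(config: GeneratorConfig, batch_index: int) -> np.random.Generator:
    # One root seed streams per-batch generators deterministically.
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), int(batch_index)]))


def simulate_batch(
    config: GeneratorConfig,
    library: Sequence[SaponinRef],
    curves: Sequence[CalibrationCurve],
    batch_index: int = 0,
) -> tuple[Chromatogram, pd.DataFrame]:
    """Simulate one batch; returns the trace and its ground-truth peak table.

    The truth table carries, per peak, the realized apex retention time, the
    noiseless analytic peak area, and the assay concentration (ug/ml) that
    area corresponds to on the peak's assigned calibration line.  Contents
    whose calibration line would imply a non-positive area are clipped to
    ``area_floor`` (or rejected when ``on_nonpositive_area='error'``); the
    truth table always reflects the area actually simulated.
    """
    rng = _batch_rng(config, batch_index)
    contents = dict(config.true_contents) if config.true_contents is not None \
        else default_true_contents()
    curve_by_id = {c.curve_id: c for c in curves}

    t = np.arange(
        config.t_start,
        config.t_end + 0.5 * config.sampling_interval,
        config.sampling_interval,
    )
    y = np.zeros_like(t)

    batch_shift = rng.normal(0.0, config.rt_jitter_sd) if config.rt_jitter_sd else 0.0
    rows = []
    for sap in sorted(library, key=lambda s: s.peak_no):
        frac = contents.get(sap.peak_no, 0.0)
        curve = curve_by_id[sap.curve_id]
        conc = frac * config.dilution_to * 1000.0  # ug/ml in the assay solution
        base_area = curve.area(conc)
        if base_area <= 0 and frac > 0:
            if config.on_nonpositive_area == "error":
                raise GeneratorError(
                    f"peak {sap.peak_no} ({sap.name}): content {frac:.4f} implies "
                    f"non-positive area {base_area:.2f} on curve {curve.curve_id!r}"
                )
            base_area = config.area_floor
        if frac <= 0:
            continue
        mult = float(np.exp(rng.normal(0.0, config.area_cv))) if config.area_cv else 1.0
        area = base_area * mult
        jitter = rng.normal(0.0, config.rt_jitter_peak_sd) if config.rt_jitter_peak_sd else 0.0
        rt = sap.retention_time + batch_shift + jitter
        span = 10.0 * config.peak_width_sd + 12.0 * config.emg_tau
        mask = (t >= rt - span) & (t <= rt + span)
        y[mask] += emg_profile(t[mask], area, rt, config.peak_width_sd, config.emg_tau)
        rows.append(
            {
                "peak_no": sap.peak_no,
                "apex_rt": rt,
                "area": area,
                "concentration": curve.concentration(area),
                "content_percent": 100.0
                * curve.concentration(area)
                / (config.dilution_to * 1000.0),
                "curve_id": curve.curve_id,
            }
        )

    if config.solvent_front:
        y += _solvent_front(t, config.solvent_front, rng)
    if config.baseline_amplitude:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        y += config.baseline_amplitude * (
            0.5 * np.sin(2.0 * np.pi * t / 75.0 + phase) + 0.5 * t / max(config.t_end, 1.0)
        )
    if config.noise_sd:
        y += rng.normal(0.0, config.noise_sd, size=t.size)

    meta = {
        "batch_id": f"batch{batch_index:02d}",
        "wavelength_nm": 203,
        "sampling_interval_min": config.sampling_interval,
        "seed": config.seed,
    }
    truth = pd.DataFrame(
        rows,
        columns=["peak_no", "apex_rt", "area", "concentration", "content_percent", "curve_id"],
    )
    return Chromatogram(t, y, meta), truth


def simulate_run(
    config: GeneratorConfig,
    library: Sequence[SaponinRef],
    curves: Sequence[CalibrationCurve],
) -> list[tuple[Chromatogram, pd.DataFrame]]:
    """Simulate ``config.n_batches`` batches under one root seed."""
    return [
        simulate_batch(config, library, curves, i) for i in range(config.n_batches)
    ]


def simulate_msn(
    saponin: SaponinRef,
    tol_noise: float = 0.0,
    rng: Optional[np.random.Generator] = None,
):
    """Clean (or mass-perturbed) MS^n spectrum from a library entry.

    Fragments are the prefix sums of the stored glycan-loss order subtracted
    from the deprotonated molecular ion, optionally perturbed by at most
    ``tol_noise`` Da each.
    """
    from .msannotate import MSnSpectrum

    fragments = np.array(saponin.loss_ladder, dtype=float)
    if tol_noise > 0:
        rng = rng or np.random.default_rng()
        fragments = fragments + rng.uniform(-tol_noise, tol_noise, size=fragments.size)
    return MSnSpectrum(
        precursor_mz=float(saponin.deprotonated_mass),
        fragments=tuple(float(f) for f in fragments),
    )
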