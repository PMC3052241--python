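import pytest

from saponinfp import (
    GeneratorConfig,
    detect_peaks,
    load_library,
    simulate_run,
)


@pytest.fixture(scope="session")
def library():
    saponins, curves = load_library()
    return saponins, curves


@pytest.fixture(scope="session")
def default_run(library):
    """Ten simulated batches at the default study conditions (seed 1)."""
    saponins, curves = library
    cfg = GeneratorConfig(seed=1)
    out = simulate_run(cfg, saponins, curves)
    chroms = [c for c, _ in out]
    truths = [t for _, t in out]
    peak_lists = {c.meta["batch_id"]: detect_peaks(c) for c in chroms}
    return cfg, chroms, truths, peak_lists


@pytest.fixture(scope="session")
def noiseless_run(library):
    """Ten batches without detector noise, drift or solvent front."""
    saponins, curves = library
    cfg = GeneratorConfig(seed=1, noise_sd=0.0, baseline_amplitude=0.0, solvent_front=0.0)
    out = simulate_run(cfg, saponins, curves)
    chroms = [c for c, _ in out]
    truths = [t for _, t in out]
    peak_lists = {c.meta["batch_id"]: detect_peaks(c) for c in chroms}
    return cfg, chroms, truths, peak_lists
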