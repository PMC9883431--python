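import numpy as np
import pytest

import zegselect as z


@pytest.fixture(scope="session")
def lqts() -> z.AmpliconReference:
    return z.load_locus("toyLQTS")


@pytest.fixture(scope="session")
def brs() -> z.AmpliconReference:
    return z.load_locus("toyBrS")


@pytest.fixture(scope="session")
def small_experiment(brs):
    """A small paired ZEG/WE simulation processed through the full pipeline."""
    params = z.SimulationParams(n_embryos=10, read_depth=400, seed=5)
    exp = z.simulate_experiment(params, brs)
    result = z.process_experiment(exp, min_total_reads=50)
    return exp, result


@pytest.fixture(scope="session")
def noiseless_experiment(lqts):
    """Zero-sequencing-error simulation for exact recovery checks."""
    params = z.SimulationParams(
        n_embryos=6, read_depth=400, seq_error_rate=0.0, seed=9
    )
    exp = z.simulate_experiment(params, lqts, kinds=("WE",))
    result = z.process_experiment(exp, min_total_reads=50)
    return exp, result


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
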