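import numpy as np
import pytest

from dva_cea import default_parameters, run_scenario


@pytest.fixture(scope="session")
def params():
    """The shipped base-case parameter set (treat as read-only; copy to mutate)."""
    return default_parameters()


@pytest.fixture(scope="session")
def base_scenario(params):
    """Deterministic base-case run of both arms at shipped settings."""
    return run_scenario(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def microsimulate(matrix: np.ndarray, init_counts: np.ndarray, n_cycles: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Independent agent-based oracle: integer agents moved by multinomial
    draws from each state's transition row."""
    counts = np.asarray(init_counts, dtype=np.int64)
    for _ in range(n_cycles):
        new = np.zeros_like(counts)
        for s in range(matrix.shape[0]):
            if counts[s] > 0:
                new += rng.multinomial(counts[s], matrix[s])
        counts = new
    return counts


def integer_init(shares: np.ndarray, n_agents: int) -> np.ndarray:
    """Deterministic largest-remainder rounding of shares to integer counts."""
    raw = shares * n_agents
    base = np.floor(raw).astype(np.int64)
    remainder = n_agents - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:remainder]] += 1
    return base
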