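import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from spatialpd.lattice import C, D, LatticeState, PayoffParams, neighbors, pair_payoff


@pytest.fixture
def default_payoff():
    return PayoffParams(T=1.3)


def brute_force_payoffs(state: LatticeState, params: PayoffParams) -> np.ndarray:
    """Independent payoff oracle: explicit double loop over sites and neighbors."""
    L = state.L
    out = np.zeros((L, L))
    for r in range(L):
        for c in range(L):
            for nb in neighbors(state, (r, c)):
                mine, _ = pair_payoff(int(state.cells[r, c]), int(state.cells[nb]), params)
                out[r, c] += mine
    return out


def lattice_from_rows(rows) -> LatticeState:
    return LatticeState(np.array(rows, dtype=np.uint8))
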