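"""Independent oracles used by the test suite.

These deliberately do not share code with the simulation path: the
pool-exchange oracle is a direct Gillespie SSA on the aggregate
surface-count birth-death chain, and the channel oracle is the
matrix-exponential solution of the gating master equation.
"""

import numpy as np
from scipy.linalg import expm


def gillespie_pool_exchange(n_total: int, n_surface0: int, k_endo: float,
                            k_exo: float, t_end: float,
                            rng: np.random.Generator) -> int:
    """Exact SSA for N independent two-state (surface/internal) particles,
    simulated as the aggregate birth-death chain; returns the surface
    count at t_end."""
    n = n_surface0
    t = 0.0
    while True:
        rate_down = n * k_endo
        rate_up = (n_total - n) * k_exo
        total = rate_down + rate_up
        if total <= 0.0:
            return n
        t += rng.exponential(1.0 / total)
        if t > t_end:
            return n
        if rng.random() < rate_down / total:
            n -= 1
        else:
            n += 1


def channel_occupancy_ode(scheme, concentration_M: float,
                          times, start_state: int = 0) -> np.ndarray:
    """P(state, t) for a single channel in a fixed glutamate bath, from
    the matrix exponential of the generator."""
    q = scheme.generator(concentration_M)
    p0 = np.zeros(scheme.n_states)
    p0[start_state] = 1.0
    return np.vstack([expm(q * t) @ p0 for t in times])
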