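"""AMPAR gating scheme.

A generic multi-state Markov channel with concentration-dependent
(glutamate-binding) and first-order transitions.  The default is the
seven-state kinetic scheme fitted to CA3 AMPAR currents by Jonas, Major
and Sakmann (1993): three closed states (0, 1 and 2 glutamate bound),
one open state, and three desensitized states.  The source model used
these constants adjusted to recorded mEPSCs without publishing the
adjusted values, so the published constants are the default here and
every rate is overridable from the config file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np

AVOGADRO = 6.02214076e23
#: nm³/s per M⁻¹s⁻¹  (1 litre = 1e24 nm³)
_M_TO_NM3 = 1e24 / AVOGADRO


@dataclass(frozen=True)
class ChannelScheme:
    """Markov gating scheme.

    ``unimolecular`` lists first-order transitions ``(i, j, rate_per_s,
    releases_glutamate)``; transitions flagged as releasing glutamate are
    the reverse of a binding step and return one glutamate to the cleft.
    ``binding`` lists concentration-dependent transitions
    ``(i, j, kon_per_M_per_s)`` that consume one glutamate.
    """

    states: tuple[str, ...]
    open_state: int
    unimolecular: tuple[tuple[int, int, float, bool], ...]
    binding: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        n = len(self.states)
        if not 0 <= self.open_state < n:
            raise ValueError("open_state out of range")
        for i, j, k, _ in self.unimolecular:
            if not (0 <= i < n and 0 <= j < n) or k < 0:
                raise ValueError("invalid unimolecular transition")
        for i, j, k in self.binding:
            if not (0 <= i < n and 0 <= j < n) or k < 0:
                raise ValueError("invalid binding transition")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def generator(self, concentration_M: float) -> np.ndarray:
        """Infinitesimal generator Q (columns sum to 0) at a fixed
        well-mixed glutamate concentration, for dP/dt = Q P."""
        n = self.n_states
        q = np.zeros((n, n))
        for i, j, k, _ in self.unimolecular:
            q[j, i] += k
        for i, j, kon in self.binding:
            q[j, i] += kon * concentration_M
        q[np.diag_indices(n)] -= q.sum(axis=0)
        return q

    def binding_step_probabilities(self, dt: float, capture_volume_nm3: float
                                   ) -> np.ndarray:
        """Per-(receptor, glutamate)-pair Bernoulli probability per step of
        length *dt* for each state, given a cylindrical capture volume.

        A glutamate inside the capture volume of a receptor in state ``i``
        fires the binding transition with probability
        ``kon · dt / (N_A · V)``, which reproduces the bimolecular rate
        ``kon·[glu]`` in the well-mixed limit (the mean number of
        glutamates in V is ``[glu]·N_A·V``).
        """
        p = np.zeros(self.n_states)
        for i, _, kon in self.binding:
            p[i] += kon * _M_TO_NM3 * dt / capture_volume_nm3
        if np.any(p >= 1.0):
            raise ValueError("binding probability per step >= 1; "
                             "reduce dt or enlarge the capture volume")
        return p

    def binding_targets(self) -> np.ndarray:
        """target[i] = state reached from i by binding (or -1)."""
        t = np.full(self.n_states, -1, dtype=np.int64)
        for i, j, _ in self.binding:
            t[i] = j
        return t

    def unimolecular_arrays(self, dt: float):
        """(from, to, per-step probability, releases_glutamate) arrays."""
        fr = np.array([u[0] for u in self.unimolecular], dtype=np.int64)
        to = np.array([u[1] for u in self.unimolecular], dtype=np.int64)
        p = 1.0 - np.exp(-np.array([u[2] for u in self.unimolecular]) * dt)
        rel = np.array([u[3] for u in self.unimolecular], dtype=np.bool_)
        return fr, to, p, rel

    def to_dict(self) -> dict[str, Any]:
        return {
            "states": list(self.states),
            "open_state": self.open_state,
            "unimolecular": [list(u) for u in self.unimolecular],
            "binding": [list(b) for b in self.binding],
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ChannelScheme":
        return cls(
            states=tuple(d["states"]),
            open_state=int(d["open_state"]),
            unimolecular=tuple((int(i), int(j), float(k), bool(r))
                               for i, j, k, r in d["unimolecular"]),
            binding=tuple((int(i), int(j), float(k)) for i, j, k in d["binding"]),
        )


def jonas_scheme() -> ChannelScheme:
    """Seven-state CA3 AMPAR scheme of Jonas et al. (1993).

    States: C0, C1, C2 (closed, 0/1/2 glutamate), O (open), D1 (singly
    bound desensitized), D2/D3 (doubly bound desensitized).
    """
    C0, C1, C2, O, D1, D2, D3 = range(7)
    return ChannelScheme(
        states=("C0", "C1", "C2", "O", "D1", "D2", "D3"),
        open_state=O,
        unimolecular=(
            (C1, C0, 4.26e3, True),    # glutamate unbinding
            (C2, C1, 3.26e3, True),
            (C2, O, 4.24e3, False),    # opening
            (O, C2, 9.00e2, False),    # closing
            (C1, D1, 2.89e3, False),   # desensitization, singly bound
            (D1, C1, 3.92e1, False),
            (D2, D1, 4.57e1, True),    # unbinding within desensitized branch
            (C2, D2, 1.72e2, False),   # desensitization, doubly bound
            (D2, C2, 7.27e-1, False),
            (D2, D3, 1.68e1, False),
            (D3, D2, 1.904e2, False),
            (O, D3, 1.77e1, False),    # desensitization from open
            (D3, O, 4.0, False),
        ),
        binding=(
            (C0, C1, 4.59e6),
            (C1, C2, 2.84e7),
            (D1, D2, 1.27e6),
        ),
    )
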