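"""Kinetic parameters, LTD perturbations and config-file handling.

Rates follow the reaction scheme of the organization phase: PSD-95 is
palmitoylated inside the nanodomain (k_palm_on/k_palm_off), palmitoylated
PSD-95 traps freely diffusing surface AMPARs (k_bind/k_unbind, the
scheme's "k4" being the unbinding side), surface AMPARs exchange with an
intracellular pool (k_endo "k8" / k_exo), and PSD-95 can be irreversibly
inactivated (k_inact, "k6") to mimic its degradation during LTD.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .geometry import SynapseGeometry


class ParameterError(ValueError):
    """Raised for invalid rate constants, counts, or config contents."""


@dataclass(frozen=True)
class KineticParams:
    """Rate constants, diffusivities and particle counts of the model.

    Units: rates 1/s, diffusivities µm²/s, lengths nm, times s.

    The printed constants (counts, palmitoylation and binding rates, the
    two AMPAR diffusivities and the phase-1 time step) are fixed by the
    source model.  The remaining values — exchange rate with the internal
    pool, PSD-95 inactivation rate, PSD-95 diffusivities and the reaction
    radius — are calibrated so that the control steady state sits at the
    reported operating point (~70 palmitoylated PSD-95 in the nanodomain,
    20–25 trapped AMPARs); the closed-form calibration is documented in
    docs/methods.md.
    """

    n_psd95: int = 200
    n_ampar_surface: int = 60
    n_ampar_internal: int = 60
    k_palm_on: float = 35.0
    k_palm_off: float = 0.7
    k_bind: float = 5.0
    k_unbind: float = 1.0           # "k4"
    k_endo: float = 0.005           # "k8"
    k_exo: float = 0.005
    k_inact: float = 0.002          # "k6"
    D_ampar_free: float = 0.5
    D_ampar_trapped: float = 0.005
    D_psd95_free: float = 0.05
    D_psd95_palm: float = 0.005
    reaction_radius: float = 25.0
    dt_org: float = 1e-3
    t_org: float = 50.0

    def __post_init__(self) -> None:
        for name in ("k_palm_on", "k_palm_off", "k_bind", "k_unbind",
                     "k_endo", "k_exo", "k_inact"):
            if getattr(self, name) < 0:
                raise ParameterError(f"rate {name} must be >= 0")
        for name in ("D_ampar_free", "D_ampar_trapped",
                     "D_psd95_free", "D_psd95_palm"):
            if getattr(self, name) < 0:
                raise ParameterError(f"diffusivity {name} must be >= 0")
        for name in ("n_psd95", "n_ampar_surface", "n_ampar_internal"):
            if getattr(self, name) < 0:
                raise ParameterError(f"count {name} must be >= 0")
        if self.D_ampar_trapped >= self.D_ampar_free:
            raise ParameterError("D_ampar_trapped must be < D_ampar_free")
        if self.dt_org <= 0:
            raise ParameterError("dt_org must be > 0")
        if self.reaction_radius <= 0:
            raise ParameterError("reaction_radius must be > 0")

    def replace(self, **kw: Any) -> "KineticParams":
        return dataclasses.replace(self, **kw)


#: multipliers applied to (k_endo, k_inact, k_unbind)
_CONDITIONS: dict[str, tuple[float, float, float]] = {
    "control": (1.0, 1.0, 1.0),
    "endo_x3": (3.0, 1.0, 1.0),
    "inact_x4": (1.0, 4.0, 1.0),
    "untrap_x4": (1.0, 1.0, 4.0),
}


@dataclass(frozen=True)
class LTDCondition:
    """A named LTD perturbation: multipliers on (k_endo, k_inact, k_unbind)."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in _CONDITIONS:
            raise ParameterError(
                f"unknown condition {self.name!r}; choose from {sorted(_CONDITIONS)}")

    @property
    def multipliers(self) -> tuple[float, float, float]:
        return _CONDITIONS[self.name]


CONDITION_NAMES = tuple(_CONDITIONS)


def apply_condition(params: KineticParams, condition: LTDCondition | str) -> KineticParams:
    """Return a copy of *params* with the condition's multipliers applied."""
    if isinstance(condition, str):
        condition = LTDCondition(condition)
    m_endo, m_inact, m_unbind = condition.multipliers
    return params.replace(
        k_endo=params.k_endo * m_endo,
        k_inact=params.k_inact * m_inact,
        k_unbind=params.k_unbind * m_unbind,
    )


# ---------------------------------------------------------------------------
# Config files

_SECTIONS = ("params", "geometry", "condition", "channel_scheme", "protocol")


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML/JSON config with optional sections ``params``,
    ``geometry``, ``condition``, ``channel_scheme`` and ``protocol``.

    Every field is optional and defaults to the values above; unknown
    sections or fields are rejected.
    """
    from .response import StimulusProtocol  # local import to avoid cycle

    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    raw = raw or {}
    if not isinstance(raw, Mapping):
        raise ParameterError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ParameterError(f"unknown config sections: {sorted(unknown)}")

    def build(cls, section):
        data = dict(raw.get(section, {}) or {})
        names = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - names
        if bad:
            raise ParameterError(f"unknown keys in {section!r}: {sorted(bad)}")
        if "nanodomain_center" in data:
            data["nanodomain_center"] = tuple(data["nanodomain_center"])
        return cls(**data)

    out: dict[str, Any] = {
        "params": build(KineticParams, "params"),
        "geometry": build(SynapseGeometry, "geometry"),
        "protocol": build(StimulusProtocol, "protocol"),
        "condition": LTDCondition(raw.get("condition", "control")),
    }
    if "channel_scheme" in raw:
        from .channel import ChannelScheme
        out["channel_scheme"] = ChannelScheme.from_dict(raw["channel_scheme"])
    else:
        from .channel import jonas_scheme
        out["channel_scheme"] = jonas_scheme()
    return out
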