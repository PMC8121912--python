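"""Parametric synapse geometry.

The simulated post-synaptic membrane is a set of three concentric discs:
the synaptic membrane patch, the post-synaptic density (PSD) inside it,
and a single 100 nm nanodomain (the AMPAR/PSD-95 nanocluster) inside the
PSD.  A thin slab above the membrane represents the synaptic cleft used
by the glutamate-response phase.

All lengths are in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class GeometryError(ValueError):
    """Raised when disc nesting or positivity constraints are violated."""


@dataclass(frozen=True)
class SynapseGeometry:
    """Concentric-disc synapse model.

    Parameters
    ----------
    synapse_radius:
        Radius of the membrane patch over which free AMPARs diffuse (nm).
    psd_radius:
        Radius of the disc confining free PSD-95 (nm).  Calibrated so that
        the in-nanodomain palmitoylation kinetics reproduce the observed
        steady-state accumulation of palmitoylated PSD-95 (see docs).
    nanodomain_center:
        Centre of the nanodomain disc (nm, 2D).
    nanodomain_radius:
        Radius of the nanodomain; 50 nm gives the 100 nm domain that
        corresponds to the AMPAR nanodomain.
    cleft_height:
        Height of the synaptic cleft slab used in the response phase (nm).
    """

    synapse_radius: float = 560.0
    psd_radius: float = 520.0
    nanodomain_center: tuple[float, float] = field(default=(0.0, 0.0))
    nanodomain_radius: float = 50.0
    cleft_height: float = 20.0

    def __post_init__(self) -> None:
        if min(self.synapse_radius, self.psd_radius, self.nanodomain_radius,
               self.cleft_height) <= 0:
            raise GeometryError("all radii and the cleft height must be > 0")
        cx, cy = self.nanodomain_center
        r_nd = (cx * cx + cy * cy) ** 0.5
        if r_nd + self.nanodomain_radius >= self.psd_radius:
            raise GeometryError("nanodomain disc must lie strictly inside the PSD disc")
        if self.psd_radius >= self.synapse_radius:
            raise GeometryError("PSD disc must lie strictly inside the synapse disc")

    def in_nanodomain(self, x: float, y: float) -> bool:
        cx, cy = self.nanodomain_center
        return (x - cx) ** 2 + (y - cy) ** 2 <= self.nanodomain_radius ** 2
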