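"""Organization phase: run one 50 s trial and watch the synapse assemble.

Prints the count time series of palmitoylated PSD-95 inside the
nanodomain (steady state ~70), trapped AMPARs (~20-25) and surface
AMPARs, which is the equilibrium the glutamate-response phase starts
from.
"""
from synapsim import KineticParams, SynapseGeometry, init_state, run_organization

params = KineticParams()
geometry = SynapseGeometry()
state = init_state(geometry, params, seed=1)
state, counts, _ = run_organization(state, params, t_total=50.0, record_every=5.0)

print(counts.to_string(index=False))
tail = counts[counts.t_s >= 40.0]
print(f"\nsteady state (last 10 s): "
      f"{tail.palm_psd95_nd.mean():.1f} palmitoylated PSD-95 in the nanodomain, "
      f"{tail.trapped_ampar.mean():.1f} trapped AMPARs, "
      f"{tail.surface_ampar.mean():.1f} AMPARs on the surface.")
print("Palmitoylated PSD-95 forms the trapping slots; the trapped-AMPAR "
      "count is the nanodomain content that sets the synaptic response.")
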