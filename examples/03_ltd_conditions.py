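"""LTD perturbations: tripled endocytosis vs quadrupled PSD-95 inactivation.

Runs a small paired-seed scenario sweep and prints the percent change of
the pulse-1 amplitude and of the normalized pulse responses versus
control.  Increased endocytosis depresses the response without changing
paired-pulse behaviour; PSD-95 inactivation depresses it while
facilitating later pulses (more mobile receptors replace desensitized
ones).  Use more trials for quantitative numbers.
"""
from synapsim.experiments import percent_changes, run_scenario

control = run_scenario("control", n_trials=6, base_seed=0)
for cond in ("endo_x3", "inact_x4"):
    res = run_scenario(cond, n_trials=6, base_seed=0)
    print(f"\n{cond} vs control:")
    print(percent_changes(res, control).to_string(index=False))
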