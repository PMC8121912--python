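"""Release-probability detection on a synthetic glutamate-sensor trace.

Generates a stimulus train with known Bernoulli release (p = 0.4),
applies the 3xSD-of-200-baseline-points detection rule and compares the
estimate with the ground truth.
"""
from synapsim import TraceSpec, detect_release_events, gen_trace

spec = TraceSpec(n_stimuli=100, release_probability=0.4, amplitude_sd=5.0,
                 seed=3)
trace, truth = gen_trace(spec)
successes, p_hat = detect_release_events(trace)

print(f"stimuli: {spec.n_stimuli}, true release probability: "
      f"{spec.release_probability}")
print(f"ground-truth successes: {int(truth.sum())}, detected: "
      f"{int(successes.sum())}")
print(f"estimated release probability: {p_hat:.2f}")
print("A stimulus counts as a release when the first sample after it "
      "exceeds 3 standard deviations of the 200 baseline points.")
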