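"""Glutamate-sensor trace analysis: release-probability from stimulus
trains.

Mirrors the event-detection rule used on iGluSnFR recordings sampled
every 3 ms: a stimulus counts as a successful release when the first
sample after it exceeds three standard deviations of the 200 baseline
points preceding the train.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASELINE_POINTS = 200
DETECTION_SD = 3.0


class TraceError(ValueError):
    pass


@dataclass
class FluorescenceTrace:
    """Sampled ΔF/F values with stimulus sample indices."""

    values: np.ndarray
    stimulus_indices: np.ndarray
    sampling_interval: float = 3e-3
    baseline_points: int = BASELINE_POINTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.stimulus_indices = np.asarray(self.stimulus_indices, dtype=int)
        if self.stimulus_indices.size and (
                self.stimulus_indices.min() < 0
                or self.stimulus_indices.max() >= self.values.size):
            raise TraceError("stimulus indices outside trace")
        if (self.stimulus_indices.size
                and self.stimulus_indices.min() < self.baseline_points):
            raise TraceError("baseline window must precede the first stimulus")


def detect_release_events(trace: FluorescenceTrace,
                          n_sd: float = DETECTION_SD
                          ) -> tuple[np.ndarray, float]:
    """Per-stimulus success flags and the release probability.

    A stimulus succeeds when the first sample after it exceeds
    ``n_sd × SD`` of the *baseline_points* samples before the first
    stimulus (amplitudes are read relative to the baseline mean).
    """
    if trace.stimulus_indices.size == 0:
        raise TraceError("no stimuli in trace")
    first = int(trace.stimulus_indices.min())
    if first < trace.baseline_points:
        raise TraceError(f"need {trace.baseline_points} baseline points "
                         "before the first stimulus")
    base = trace.values[first - trace.baseline_points:first]
    mu = float(np.mean(base))
    sd = float(np.std(base))
    samples = trace.values[np.minimum(trace.stimulus_indices + 1,
                                      trace.values.size - 1)]
    successes = (samples - mu) > n_sd * sd
    return successes, float(np.mean(successes))
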