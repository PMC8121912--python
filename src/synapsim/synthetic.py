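"""Synthetic-data generators for the analysis modules.

Three generators emulate the statistical structure of the experimental
inputs so the full analysis stack runs without any recording:

* switching-diffusion trajectories — two-state Markov Brownian tracks
  (mobile ~0.1 µm²/s, immobile ~0.008 µm²/s, the two populations seen in
  uPAINT D histograms) sampled at 50 Hz with additive Gaussian
  localization noise;
* blinking-emitter localization fields — emitters placed in Gaussian
  nanodomain-scale clusters over a uniform background, each producing a
  negative-binomial number of localizations jittered by the localization
  precision, with optional two-channel offsets;
* fluorescence traces — Bernoulli release per stimulus riding on
  Gaussian baseline noise with exponential decay, for the
  release-probability detector.

Every generator is deterministic under a fixed seed and returns ground
truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .clustering import LocalizationField
from .fluorescence import FluorescenceTrace
from .spt import Trajectory, TrajectorySet


class SpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# switching-diffusion trajectories


@dataclass(frozen=True)
class SwitchingDiffusionSpec:
    """Two-state (mobile/immobile) switching Brownian motion.

    Defaults place the two populations at the experimentally observed
    centres (1e-1 and 0.8e-2 µm²/s) with 30 nm localization noise at a
    50 Hz frame rate.  ``switch_on`` is the immobile->mobile rate,
    ``switch_off`` the mobile->immobile rate (1/s); the stationary mobile
    occupancy is on/(on+off).
    """

    D_mobile: float = 0.1
    D_immobile: float = 0.008
    # state dwell times of seconds (slow against the ~1 s tracks) keep
    # most tracks in a single state, giving the bimodal per-track D
    # histogram seen experimentally; stationary mobile occupancy 30%
    switch_on: float = 0.3
    switch_off: float = 0.7
    loc_noise_nm: float = 30.0
    frame_rate: float = 50.0
    mean_track_length: float = 50.0
    min_track_length: int = 10
    n_tracks: int = 100
    seed: int = 0
    start_mobile_probability: Optional[float] = None  # None -> stationary

    def __post_init__(self) -> None:
        if not (self.D_mobile > self.D_immobile >= 0):
            raise SpecError("need D_mobile > D_immobile >= 0")
        if self.loc_noise_nm < 0 or self.frame_rate <= 0:
            raise SpecError("invalid noise or frame rate")
        if self.n_tracks < 1 or self.min_track_length < 2:
            raise SpecError("invalid track counts")
        if self.switch_on < 0 or self.switch_off < 0:
            raise SpecError("switch rates must be >= 0")

    @property
    def stationary_mobile(self) -> float:
        tot = self.switch_on + self.switch_off
        return self.switch_on / tot if tot > 0 else 1.0


def gen_trajectories(spec: SwitchingDiffusionSpec
                     ) -> tuple[TrajectorySet, pd.DataFrame]:
    """Generate switching-diffusion tracks plus a ground-truth table
    (track_id, frame, mobile) of the hidden per-frame state."""
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.frame_rate
    p_on = 1.0 - np.exp(-spec.switch_on * dt)    # immobile -> mobile
    p_off = 1.0 - np.exp(-spec.switch_off * dt)  # mobile -> immobile
    p0 = (spec.stationary_mobile if spec.start_mobile_probability is None
          else spec.start_mobile_probability)
    sig_noise = spec.loc_noise_nm * 1e-3         # µm
    tracks = []
    truth_rows = []
    for tid in range(spec.n_tracks):
        n = spec.min_track_length + rng.geometric(
            1.0 / max(spec.mean_track_length - spec.min_track_length + 1, 1.0)) - 1
        mobile = np.empty(n, dtype=bool)
        mobile[0] = rng.random() < p0
        u = rng.random(n - 1)
        for k in range(1, n):
            if mobile[k - 1]:
                mobile[k] = u[k - 1] >= p_off
            else:
                mobile[k] = u[k - 1] < p_on
        d_per_frame = np.where(mobile, spec.D_mobile, spec.D_immobile)
        # step k uses the state during interval (k-1, k)
        sig_step = np.sqrt(2.0 * d_per_frame[:-1] * dt)
        steps = rng.normal(size=(n - 1, 2)) * sig_step[:, None]
        pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        pos = pos + rng.normal(scale=sig_noise, size=pos.shape) if sig_noise > 0 else pos
        frames = np.arange(n)
        tracks.append(Trajectory(track_id=tid, frames=frames,
                                 times=frames * dt, positions=pos))
        truth_rows.append(pd.DataFrame(
            {"track_id": tid, "frame": frames, "mobile": mobile}))
    truth = pd.concat(truth_rows, ignore_index=True)
    return TrajectorySet(tracks), truth


# ---------------------------------------------------------------------------
# SMLM localization fields


@dataclass(frozen=True)
class GaussianClusterSpec:
    center: tuple[float, float]
    sigma_nm: float
    n_emitters: int


@dataclass(frozen=True)
class SMLMFieldSpec:
    """Blinking-emitter field: clustered + background emitters, each
    producing ``NegBinomial`` localizations jittered by the localization
    precision."""

    field_size_nm: float = 2000.0
    background_density: float = 5e-6          # emitters / nm²
    clusters: tuple[GaussianClusterSpec, ...] = (
        GaussianClusterSpec((1000.0, 1000.0), 34.0, 20),)
    mean_locs_per_emitter: float = 12.0
    locs_dispersion: float = 5.0              # neg-binomial shape parameter
    loc_noise_nm: float = 10.0                # per axis
    channel_offset_nm: tuple[float, float] = (0.0, 0.0)
    channel: str = "ch0"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_density < 0 or self.field_size_nm <= 0:
            raise SpecError("invalid field")
        if self.mean_locs_per_emitter <= 0 or self.locs_dispersion <= 0:
            raise SpecError("invalid blinking statistics")
        for c in self.clusters:
            if not (0 <= c.center[0] <= self.field_size_nm
                    and 0 <= c.center[1] <= self.field_size_nm):
                raise SpecError("cluster centre outside field")


def gen_smlm_field(spec: SMLMFieldSpec
                   ) -> tuple[LocalizationField, pd.DataFrame]:
    """Generate a localization field plus the ground-truth emitter table
    (x, y, cluster index or -1 for background, n_locs)."""
    rng = np.random.default_rng(spec.seed)
    emitters = []
    labels = []
    n_bg = rng.poisson(spec.background_density * spec.field_size_nm ** 2)
    emitters.append(rng.random((n_bg, 2)) * spec.field_size_nm)
    labels.append(np.full(n_bg, -1))
    for ci, c in enumerate(spec.clusters):
        pts = rng.normal(loc=c.center, scale=c.sigma_nm, size=(c.n_emitters, 2))
        emitters.append(pts)
        labels.append(np.full(c.n_emitters, ci))
    em = np.vstack(emitters)
    lab = np.concatenate(labels)
    # negative binomial with mean m and shape r: p = r/(r+m)
    r = spec.locs_dispersion
    p = r / (r + spec.mean_locs_per_emitter)
    n_locs = rng.negative_binomial(r, p, size=em.shape[0])
    locs = np.repeat(em, n_locs, axis=0)
    if spec.loc_noise_nm > 0:
        locs = locs + rng.normal(scale=spec.loc_noise_nm, size=locs.shape)
    locs = locs + np.asarray(spec.channel_offset_nm)
    truth = pd.DataFrame({"x_nm": em[:, 0], "y_nm": em[:, 1],
                          "cluster": lab, "n_locs": n_locs})
    frames = rng.integers(0, 40000, size=locs.shape[0])
    return LocalizationField(points=locs, frames=frames,
                             channel=spec.channel), truth


# ---------------------------------------------------------------------------
# fluorescence traces


@dataclass(frozen=True)
class TraceSpec:
    """Stimulus-train sensor trace with Bernoulli(p) release."""

    n_stimuli: int = 50
    release_probability: float = 0.4
    amplitude_sd: float = 5.0        # response amplitude in baseline-SD units
    baseline_points: int = 200
    inter_stimulus_points: int = 50
    decay_points: float = 5.0        # exponential decay constant, samples
    baseline_sd: float = 1.0
    sampling_interval: float = 3e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.release_probability <= 1.0:
            raise SpecError("release probability must be in [0, 1]")
        if self.baseline_points < 200:
            raise SpecError("need >= 200 baseline points")
        if self.n_stimuli < 1:
            raise SpecError("need at least one stimulus")


def gen_trace(spec: TraceSpec) -> tuple[FluorescenceTrace, np.ndarray]:
    """Generate a trace plus the ground-truth per-stimulus success flags."""
    rng = np.random.default_rng(spec.seed)
    n = spec.baseline_points + spec.n_stimuli * spec.inter_stimulus_points
    values = rng.normal(scale=spec.baseline_sd, size=n)
    stim_idx = spec.baseline_points + np.arange(spec.n_stimuli) * spec.inter_stimulus_points
    successes = rng.random(spec.n_stimuli) < spec.release_probability
    amp = spec.amplitude_sd * spec.baseline_sd
    for k, s in zip(stim_idx, successes):
        if not s:
            continue
        t = np.arange(n - k - 1, dtype=float)
        values[k + 1:] += amp * np.exp(-t / spec.decay_points)
    trace = FluorescenceTrace(values=values, stimulus_indices=stim_idx,
                              sampling_interval=spec.sampling_interval,
                              baseline_points=spec.baseline_points)
    return trace, successes
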