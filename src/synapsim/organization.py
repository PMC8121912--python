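"""Phase-1 simulator: stochastic organization of PSD-95 and AMPAR.

200 PSD-95 molecules diffuse over the post-synaptic membrane, become
palmitoylated inside the nanodomain (kon = 35/s, koff = 0.7/s) where they
act as slowly mobile trapping slots; 120 AMPARs split between an
intracellular pool and the surface, diffuse laterally (0.5 µm²/s free,
0.005 µm²/s trapped), bind palmitoylated PSD-95 (kon = 5/s per
receptor-slot contact, koff = 1/s), exchange with the internal pool, and
PSD-95 can be irreversibly inactivated.  Dynamics are advanced with a
fixed-step tau-leap: each particle takes a Gaussian step of variance
2·D·dt per axis with reflective confinement, and each first-order
reaction channel fires with probability 1 - exp(-k·dt) per step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels as K
from .geometry import SynapseGeometry
from .params import KineticParams, ParameterError, apply_condition  # noqa: F401

PSD_STATE_NAMES = ("FREE", "PALMITOYLATED", "BOUND", "INACTIVE")
AMPAR_STATE_NAMES = ("INTERNAL", "SURFACE_FREE", "TRAPPED")

_UM2_TO_NM2 = 1.0e6  # µm²/s -> nm²/s


def _derive_seed(seed: int, counter: int) -> int:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(counter),))
    return int(ss.generate_state(1)[0] % np.uint32(2**31 - 1))


@dataclass
class SimState:
    """Positions and discrete states of every particle, plus the clock.

    ``psd_state``: 0 FREE, 1 PALMITOYLATED, 2 BOUND, 3 INACTIVE.
    ``ampar_state``: 0 INTERNAL, 1 SURFACE_FREE, 2 TRAPPED.
    Positions are nm; internal AMPARs have undefined (NaN) positions.
    """

    geometry: SynapseGeometry
    psd_pos: np.ndarray
    psd_state: np.ndarray
    psd_partner: np.ndarray
    ampar_pos: np.ndarray
    ampar_state: np.ndarray
    ampar_partner: np.ndarray
    clock: float = 0.0
    seed: int = 0
    rng_counter: int = 0

    def copy(self) -> "SimState":
        return SimState(self.geometry, self.psd_pos.copy(), self.psd_state.copy(),
                        self.psd_partner.copy(), self.ampar_pos.copy(),
                        self.ampar_state.copy(), self.ampar_partner.copy(),
                        self.clock, self.seed, self.rng_counter)

    def next_seed(self) -> int:
        s = _derive_seed(self.seed, self.rng_counter)
        self.rng_counter += 1
        return s

    # -- convenience counts ------------------------------------------------
    def n_trapped(self) -> int:
        return int(np.sum(self.ampar_state == K.AMP_TRAPPED))

    def n_surface(self) -> int:
        return int(np.sum(self.ampar_state != K.AMP_INTERNAL))

    def n_active_psd95(self) -> int:
        return int(np.sum(self.psd_state != K.PSD_INACT))

    def n_palmitoylated_in_nanodomain(self) -> int:
        palm = (self.psd_state == K.PSD_PALM) | (self.psd_state == K.PSD_BOUND)
        cx, cy = self.geometry.nanodomain_center
        d2 = (self.psd_pos[:, 0] - cx) ** 2 + (self.psd_pos[:, 1] - cy) ** 2
        return int(np.sum(palm & (d2 <= self.geometry.nanodomain_radius ** 2)))

    def check_invariants(self, params: KineticParams) -> None:
        """Assert conservation, pairing consistency and containment."""
        n_amp = params.n_ampar_surface + params.n_ampar_internal
        assert self.ampar_state.shape[0] == n_amp, "AMPAR count not conserved"
        assert self.psd_state.shape[0] == params.n_psd95, "PSD-95 count not conserved"
        trapped = np.flatnonzero(self.ampar_state == K.AMP_TRAPPED)
        bound = np.flatnonzero(self.psd_state == K.PSD_BOUND)
        assert len(trapped) == len(bound), "trapped/bound mismatch"
        for i in trapped:
            j = self.ampar_partner[i]
            assert j >= 0 and self.psd_state[j] == K.PSD_BOUND
            assert self.psd_partner[j] == i, "pairing not mutual"
        surf = self.ampar_state != K.AMP_INTERNAL
        r = np.hypot(self.ampar_pos[surf, 0], self.ampar_pos[surf, 1])
        assert np.all(r <= self.geometry.synapse_radius * (1 + 1e-12)), \
            "surface AMPAR outside synapse disc"
        r_psd = np.hypot(self.psd_pos[:, 0], self.psd_pos[:, 1])
        assert np.all(r_psd <= self.geometry.synapse_radius * (1 + 1e-12))


def init_state(geometry: SynapseGeometry, params: KineticParams, seed: int) -> SimState:
    """Release the particles: PSD-95 uniformly in the PSD disc, surface
    AMPARs uniformly in the synapse disc, the rest in the internal pool."""
    rng = np.random.default_rng(_derive_seed(seed, 0))
    n_psd = params.n_psd95
    n_amp = params.n_ampar_surface + params.n_ampar_internal

    def disc(n, radius):
        r = radius * np.sqrt(rng.random(n))
        th = 2 * np.pi * rng.random(n)
        return np.column_stack([r * np.cos(th), r * np.sin(th)])

    psd_pos = disc(n_psd, geometry.psd_radius)
    amp_pos = np.full((n_amp, 2), np.nan)
    amp_pos[:params.n_ampar_surface] = disc(params.n_ampar_surface,
                                            geometry.synapse_radius)
    amp_state = np.full(n_amp, K.AMP_INTERNAL, dtype=np.int8)
    amp_state[:params.n_ampar_surface] = K.AMP_FREE
    return SimState(
        geometry=geometry,
        psd_pos=psd_pos,
        psd_state=np.zeros(n_psd, dtype=np.int8),
        psd_partner=np.full(n_psd, -1, dtype=np.int64),
        ampar_pos=amp_pos,
        ampar_state=amp_state,
        ampar_partner=np.full(n_amp, -1, dtype=np.int64),
        clock=0.0,
        seed=int(seed),
        rng_counter=1,
    )


def _geom_vec(g: SynapseGeometry) -> np.ndarray:
    return np.array([g.synapse_radius, g.psd_radius,
                     g.nanodomain_center[0], g.nanodomain_center[1],
                     g.nanodomain_radius])


def _prob_vec(p: KineticParams, dt: float) -> np.ndarray:
    rates = np.array([p.k_palm_on, p.k_palm_off, p.k_bind, p.k_unbind,
                      p.k_endo, p.k_exo, p.k_inact])
    return 1.0 - np.exp(-rates * dt)


def _sig_vec(p: KineticParams, dt: float) -> np.ndarray:
    d = np.array([p.D_ampar_free, p.D_ampar_trapped,
                  p.D_psd95_free, p.D_psd95_palm]) * _UM2_TO_NM2
    return np.sqrt(2.0 * d * dt)


_NO_TRACK = (np.empty((0, 0, 2)), np.empty((0, 0), dtype=np.int8))


def step_organization(state: SimState, params: KineticParams, dt: float) -> SimState:
    """Advance one tau-leap step of length *dt* and return the new state."""
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    out = state.copy()
    counts = np.zeros((0, 5), dtype=np.int64)
    K.org_run(out.psd_pos, out.psd_state, out.psd_partner,
              out.ampar_pos, out.ampar_state, out.ampar_partner,
              _geom_vec(state.geometry), _prob_vec(params, dt),
              _sig_vec(params, dt), params.reaction_radius,
              1, 0, counts, 0, 0, *_NO_TRACK, out.next_seed())
    out.clock = state.clock + dt
    return out


@dataclass
class TrackRecording:
    """AMPAR positions sampled at a fixed interval during a run."""

    times: np.ndarray            # s
    positions: np.ndarray        # (n_frames, n_ampar, 2) nm
    states: np.ndarray           # (n_frames, n_ampar) int8
    frame_interval: float        # s


def run_organization(state: SimState, params: KineticParams,
                     t_total: float, record_every: float = 0.5,
                     track_interval: Optional[float] = None,
                     track_window: Optional[float] = None,
                     ) -> tuple[SimState, pd.DataFrame, Optional[TrackRecording]]:
    """Run the organization phase for *t_total* seconds.

    Returns the final state, a count time series (columns ``t_s``,
    ``palm_psd95_nd``, ``trapped_ampar``, ``surface_ampar``,
    ``active_psd95``, including the initial sample), and — when
    *track_interval* is given — AMPAR positions sampled at that interval
    over the final *track_window* seconds (whole run if None).
    """
    dt = params.dt_org
    n_steps = int(round(t_total / dt))
    if abs(n_steps * dt - t_total) > 1e-9:
        raise ParameterError("t_total must be a multiple of dt_org")

    out = state.copy()
    row0 = (0, state.n_palmitoylated_in_nanodomain(), state.n_trapped(),
            state.n_surface(), state.n_active_psd95())
    if n_steps == 0:
        df = pd.DataFrame([row0], columns=["step", "palm_psd95_nd", "trapped_ampar",
                                           "surface_ampar", "active_psd95"])
        df.insert(0, "t_s", state.clock)
        return out, df.drop(columns="step"), None

    record_stride = max(1, int(round(record_every / dt)))
    n_rec = n_steps // record_stride
    counts = np.zeros((n_rec, 5), dtype=np.int64)

    if track_interval is not None:
        track_stride = max(1, int(round(track_interval / dt)))
        window = t_total if track_window is None else min(track_window, t_total)
        track_start = n_steps - int(round(window / dt)) + track_stride
        if track_start < 1:
            track_start = track_stride
        n_frames = (n_steps - track_start) // track_stride + 1
        track_pos = np.zeros((n_frames, out.ampar_state.shape[0], 2))
        track_state = np.zeros((n_frames, out.ampar_state.shape[0]), dtype=np.int8)
    else:
        track_stride = 0
        track_start = 0
        track_pos, track_state = _NO_TRACK

    K.org_run(out.psd_pos, out.psd_state, out.psd_partner,
              out.ampar_pos, out.ampar_state, out.ampar_partner,
              _geom_vec(state.geometry), _prob_vec(params, dt),
              _sig_vec(params, dt), params.reaction_radius,
              n_steps, record_stride, counts,
              track_start, track_stride, track_pos, track_state,
              out.next_seed())
    out.clock = state.clock + n_steps * dt

    rows = np.vstack([np.array(row0, dtype=np.int64), counts])
    df = pd.DataFrame(rows, columns=["step", "palm_psd95_nd", "trapped_ampar",
                                     "surface_ampar", "active_psd95"])
    df.insert(0, "t_s", state.clock + df.pop("step") * dt)

    recording = None
    if track_interval is not None:
        times = state.clock + (track_start + track_stride *
                               np.arange(track_pos.shape[0])) * dt
        recording = TrackRecording(times=times, positions=track_pos,
                                   states=track_state,
                                   frame_interval=track_stride * dt)
    return out, df, recording


def export_surface_trajectories(recording: TrackRecording,
                                frame_interval: Optional[float] = None,
                                max_track_length: Optional[int] = None):
    """Split each AMPAR's recorded positions into surface-residence
    trajectories (internal episodes split tracks), in the SPT module's
    Trajectory format with positions in µm.

    *max_track_length* additionally chops long surface residencies into
    segments of at most that many frames, emulating the
    photobleaching-limited track lengths of single-particle-tracking
    acquisitions; without it, tracks spanning many trap/untrap cycles
    average into a single D and the mobile/immobile dichotomy is lost.
    """
    from .spt import Trajectory, TrajectorySet

    if recording is None or recording.positions.shape[0] == 0:
        return TrajectorySet([])
    dt = frame_interval or recording.frame_interval
    n_frames, n_amp, _ = recording.positions.shape
    tracks = []
    tid = 0
    for i in range(n_amp):
        on_surface = recording.states[:, i] != K.AMP_INTERNAL
        # contiguous surface runs
        edges = np.flatnonzero(np.diff(on_surface.astype(np.int8)))
        starts = [0] if on_surface[0] else []
        starts += [e + 1 for e in edges if on_surface[e + 1]]
        ends = [e + 1 for e in edges if on_surface[e]]
        if on_surface[-1]:
            ends.append(n_frames)
        for s0, e0 in zip(starts, ends):
            step = max_track_length or (e0 - s0)
            for s in range(s0, e0, step):
                e = min(s + step, e0)
                if e - s < 2:
                    continue
                frames = np.arange(s, e)
                tracks.append(Trajectory(
                    track_id=tid,
                    frames=frames,
                    times=frames * dt,
                    positions=recording.positions[s:e, i, :] * 1e-3,  # nm->µm
                ))
                tid += 1
    return TrajectorySet(tracks)
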