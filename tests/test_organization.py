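"""Organization-phase simulator: initialization, dynamics, equilibria."""

import numpy as np
import pytest
from scipy import stats

from synapsim.geometry import GeometryError, SynapseGeometry
from synapsim.organization import (TrackRecording,
                                   export_surface_trajectories, init_state,
                                   run_organization, step_organization)
from synapsim.params import (KineticParams, LTDCondition, ParameterError,
                             apply_condition)

from oracles import gillespie_pool_exchange


def quiet_params(**kw):
    """All reactions off, (near-)zero diffusion, unless overridden."""
    base = dict(k_palm_on=0.0, k_palm_off=0.0, k_bind=0.0, k_unbind=0.0,
                k_endo=0.0, k_exo=0.0, k_inact=0.0,
                D_ampar_free=1e-12, D_ampar_trapped=1e-13,
                D_psd95_free=0.0, D_psd95_palm=0.0)
    base.update(kw)
    return KineticParams(**base)


class TestInitState:
    def test_counts_and_placement(self, geometry, params):
        s = init_state(geometry, params, seed=1)
        assert s.psd_state.shape[0] == 200
        assert s.ampar_state.shape[0] == 120
        assert s.n_surface() == 60
        assert np.sum(s.ampar_state == 0) == 60          # internal pool
        r_psd = np.hypot(*s.psd_pos.T)
        assert np.all(r_psd <= geometry.psd_radius)
        surf = s.ampar_state != 0
        r_amp = np.hypot(*s.ampar_pos[surf].T)
        assert np.all(r_amp <= geometry.synapse_radius)
        assert np.all(np.isnan(s.ampar_pos[~surf]))
        assert s.clock == 0.0

    def test_empty_psd95(self, geometry):
        p = KineticParams(n_psd95=0)
        s = init_state(geometry, p, seed=1)
        assert s.psd_state.shape[0] == 0
        assert s.n_surface() == 60

    def test_same_seed_bit_identical(self, geometry, params):
        a = init_state(geometry, params, seed=7)
        b = init_state(geometry, params, seed=7)
        assert np.array_equal(a.psd_pos, b.psd_pos)
        assert np.array_equal(a.ampar_pos[a.ampar_state != 0],
                              b.ampar_pos[b.ampar_state != 0])

    def test_invalid_counts_rejected(self):
        with pytest.raises(ParameterError):
            KineticParams(n_psd95=-1)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(GeometryError):
            SynapseGeometry(psd_radius=600.0, synapse_radius=560.0)
        with pytest.raises(GeometryError):
            SynapseGeometry(nanodomain_radius=0.0)
        with pytest.raises(GeometryError):
            SynapseGeometry(nanodomain_center=(500.0, 0.0))


class TestStepOrganization:
    def test_null_dynamics_leaves_state(self, geometry):
        p = quiet_params()
        s = init_state(geometry, p, seed=2)
        s2 = step_organization(s, p, p.dt_org)
        assert np.allclose(s2.psd_pos, s.psd_pos, atol=1e-3)
        surf = s.ampar_state != 0
        assert np.allclose(s2.ampar_pos[surf], s.ampar_pos[surf], atol=1e-3)
        assert np.array_equal(s2.psd_state, s.psd_state)
        assert np.array_equal(s2.ampar_state, s.ampar_state)
        assert s2.clock == pytest.approx(p.dt_org)

    def test_bad_dt_rejected(self, geometry, params):
        s = init_state(geometry, params, seed=2)
        with pytest.raises(ParameterError):
            step_organization(s, params, 0.0)

    def test_invariants_hold_under_fast_kinetics(self, geometry):
        """Conservation, mutual pairing and containment after every step,
        with all reaction channels firing frequently."""
        p = KineticParams(k_endo=5.0, k_exo=5.0, k_inact=0.5, k_unbind=5.0,
                          k_bind=20.0, D_ampar_free=1.0)
        s = init_state(geometry, p, seed=3)
        for _ in range(60):
            s = step_organization(s, p, 5e-3)
            s.check_invariants(p)
        assert s.n_active_psd95() < 200      # inactivation actually fired


class TestPoolExchange:
    """Endo/exocytosis alone is a two-state exchange: closed-form
    occupancy and agreement with a Gillespie oracle."""

    def run_surface_fraction(self, geometry, k_endo, k_exo, seeds, t=30.0):
        p = quiet_params(k_endo=k_endo, k_exo=k_exo, D_ampar_free=1e-9)
        vals = []
        for seed in seeds:
            s = init_state(geometry, p, seed)
            _, counts, _ = run_organization(s, p, t, record_every=0.2)
            tail = counts[counts.t_s >= 10.0]    # >> 1/(k_endo+k_exo)
            vals.append(tail.surface_ampar.mean() / 120.0)
        return np.asarray(vals)

    def test_symmetric_rates_give_half(self, geometry):
        vals = self.run_surface_fraction(geometry, 0.5, 0.5, range(8))
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.5) < 3 * max(se, 2e-3)

    def test_tripled_endocytosis_gives_quarter(self, geometry):
        # k_exo/(3 k_endo0 + k_exo) = 0.25
        vals = self.run_surface_fraction(geometry, 1.5, 0.5, range(8))
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.25) < 3 * max(se, 2e-3)

    def test_occupancy_distribution_matches_gillespie(self, geometry, rng):
        """Engine occupancy histogram vs an exact SSA, chi-square on a
        small instance."""
        k_endo, k_exo, t_end, n_rep = 0.8, 0.5, 4.0, 250
        p = quiet_params(k_endo=k_endo, k_exo=k_exo,
                         n_ampar_surface=6, n_ampar_internal=6,
                         n_psd95=0, D_ampar_free=1e-9)
        engine = []
        for seed in range(n_rep):
            s = init_state(geometry, p, seed)
            s2, _, _ = run_organization(s, p, t_end, record_every=10.0)
            engine.append(s2.n_surface())
        oracle = [gillespie_pool_exchange(12, 6, k_endo, k_exo, t_end, rng)
                  for _ in range(n_rep)]
        bins = [-0.5, 2.5, 4.5, 5.5, 6.5, 7.5, 9.5, 12.5]
        h_engine, _ = np.histogram(engine, bins)
        h_oracle, _ = np.histogram(oracle, bins)
        table = np.vstack([h_engine, h_oracle])
        table = table[:, table.sum(axis=0) > 0]
        _, pval, _, _ = stats.chi2_contingency(table)
        assert pval > 0.001


class TestPalmitoylationBalance:
    def test_frozen_in_nanodomain_fraction(self):
        """With diffusion frozen and PSD-95 confined to (almost) the
        nanodomain, the palmitoylated fraction approaches
        kon/(kon+koff)."""
        g = SynapseGeometry(synapse_radius=60.0, psd_radius=51.0,
                            nanodomain_radius=50.0)
        p = quiet_params(k_palm_on=35.0, k_palm_off=0.7,
                         n_ampar_surface=0, n_ampar_internal=0)
        target = 35.0 / 35.7
        fracs = []
        for seed in range(5):
            s = init_state(g, p, seed)
            cx, cy = g.nanodomain_center
            in_nd = (np.hypot(s.psd_pos[:, 0] - cx, s.psd_pos[:, 1] - cy)
                     <= g.nanodomain_radius)
            s2, _, _ = run_organization(s, p, 2.0, record_every=5.0)
            palm = np.isin(s2.psd_state, (1, 2))
            fracs.append(palm[in_nd].mean())
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - target) < 3 * max(se, 0.005)


class TestTrappingMonotonicity:
    @staticmethod
    def steady_trapped(geometry, seeds, **kw):
        p = KineticParams(**kw)
        vals = []
        for seed in seeds:
            s = init_state(geometry, p, seed)
            _, counts, _ = run_organization(s, p, 20.0, record_every=0.5)
            vals.append(counts[counts.t_s >= 10.0].trapped_ampar.mean())
        return float(np.mean(vals))

    def test_nonincreasing_in_unbinding_rate(self, geometry):
        t = [self.steady_trapped(geometry, range(4), k_unbind=k)
             for k in (0.5, 1.0, 2.0)]
        assert t[0] >= t[1] >= t[2]

    def test_nondecreasing_in_binding_rate(self, geometry):
        t = [self.steady_trapped(geometry, range(4), k_bind=k)
             for k in (1.0, 5.0, 20.0)]
        assert t[0] <= t[1] <= t[2]


class TestApplyCondition:
    def test_control_is_identity(self, params):
        assert apply_condition(params, "control") == params

    @pytest.mark.parametrize("name,field,factor", [
        ("endo_x3", "k_endo", 3.0),
        ("inact_x4", "k_inact", 4.0),
        ("untrap_x4", "k_unbind", 4.0),
    ])
    def test_multiplier_applied_to_single_rate(self, params, name, field, factor):
        out = apply_condition(params, name)
        assert getattr(out, field) == pytest.approx(getattr(params, field) * factor)
        untouched = {"k_endo", "k_inact", "k_unbind"} - {field}
        for f in untouched:
            assert getattr(out, f) == getattr(params, f)
        assert out.k_palm_on == params.k_palm_on

    def test_unknown_condition_rejected(self):
        with pytest.raises(ParameterError):
            LTDCondition("endo_x9")


class TestRunOrganization:
    def test_zero_duration_returns_initial(self, geometry, params):
        s = init_state(geometry, params, seed=1)
        s2, counts, _ = run_organization(s, params, 0.0)
        assert len(counts) == 1
        assert counts.surface_ampar.iloc[0] == 60

    def test_non_multiple_duration_rejected(self, geometry, params):
        s = init_state(geometry, params, seed=1)
        with pytest.raises(ParameterError):
            run_organization(s, params, 0.0105)

    def test_determinism_byte_for_byte(self, geometry, params):
        s = init_state(geometry, params, seed=11)
        a, ca, _ = run_organization(s, params, 2.0, record_every=0.5)
        b, cb, _ = run_organization(s, params, 2.0, record_every=0.5)
        assert ca.equals(cb)
        assert np.array_equal(a.psd_pos, b.psd_pos)
        assert np.array_equal(a.ampar_pos[a.ampar_state != 0],
                              b.ampar_pos[b.ampar_state != 0])
        assert np.array_equal(a.psd_state, b.psd_state)

    def test_conservation_on_every_recorded_frame(self, geometry):
        p = KineticParams(k_endo=1.0, k_exo=1.0, k_inact=0.1)
        s = init_state(geometry, p, seed=4)
        _, counts, _ = run_organization(s, p, 5.0, record_every=0.1)
        assert (counts.surface_ampar <= 120).all()
        assert (counts.trapped_ampar <= counts.surface_ampar).all()
        assert (counts.active_psd95 <= 200).all()
        assert (counts.active_psd95.diff().dropna() <= 0).all()  # irreversible


class TestExportTrajectories:
    @staticmethod
    def recording(states, positions, dt=0.02):
        n_frames, n_amp = states.shape
        return TrackRecording(times=np.arange(n_frames) * dt,
                              positions=positions, states=states,
                              frame_interval=dt)

    def test_internal_episode_splits_track(self):
        states = np.ones((10, 1), dtype=np.int8)
        states[4:6, 0] = 0                      # internal episode
        pos = np.random.default_rng(0).normal(size=(10, 1, 2))
        tracks = export_surface_trajectories(self.recording(states, pos))
        assert len(tracks) == 2
        assert [len(t) for t in tracks.tracks] == [4, 4]

    def test_continuous_surface_is_single_track(self):
        states = np.ones((100, 1), dtype=np.int8)
        pos = np.zeros((100, 1, 2))
        tracks = export_surface_trajectories(self.recording(states, pos))
        assert len(tracks) == 1
        assert len(tracks[0]) == 100
        assert np.allclose(tracks[0].positions, 0.0)   # zero displacement

    def test_empty_recording_gives_empty_set(self):
        rec = TrackRecording(times=np.empty(0),
                             positions=np.empty((0, 0, 2)),
                             states=np.empty((0, 0), dtype=np.int8),
                             frame_interval=0.02)
        assert len(export_surface_trajectories(rec)) == 0

    def test_exported_positions_are_micrometres(self, geometry, params):
        s = init_state(geometry, params, seed=5)
        _, _, rec = run_organization(s, params, 2.0, record_every=0.5,
                                     track_interval=0.02, track_window=1.0)
        tracks = export_surface_trajectories(rec)
        assert len(tracks) > 0
        r = np.hypot(*np.vstack([t.positions for t in tracks.tracks]).T)
        assert np.all(r <= geometry.synapse_radius * 1e-3 + 1e-9)
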