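"""SBR/CSTR scenario engine: mixing, decanting, washout, refinement, observation."""

import numpy as np
import pytest

from asmcal.fixtures import (cstr_config, cstr_initial_state, sbr_influent,
                             sbr_initial_state, sbr_schedule)
from asmcal.scenarios import (CSTRConfig, Forcing, Phase, SBRSchedule, observe,
                              simulate_cstr, simulate_sbr)

MINUTE = 1.0 / 1440.0
HOUR = 1.0 / 24.0


def _short_schedule(composition, feed_vol=7.0, v0=7.0):
    return SBRSchedule(
        phases=(
            Phase("feed", 3 * MINUTE, volume=feed_vol, composition=composition),
            Phase("aerobic", 30 * MINUTE, do=2.0),
            Phase("anoxic", 30 * MINUTE),
            Phase("settle", 20 * MINUTE),
            Phase("decant", 6 * MINUTE, volume=feed_vol),
            Phase("idle", 1 * MINUTE),
        ),
        volume0=v0,
    )


class TestSBR:
    def test_feed_mixing_formula_for_inert_system(self, inert_model):
        """Without reactions, feeding obeys (V0 C0 + Vf Cf)/(V0 + Vf) exactly."""
        model = inert_model
        influent = sbr_influent()
        sched = _short_schedule(influent)
        init = sbr_initial_state(model)
        traj = simulate_sbr(model, sched, model.params.defaults, init)
        i_end_feed = np.searchsorted(traj.t, 3 * MINUTE)
        c_in = np.zeros(len(model.components))
        for k, v in influent.items():
            c_in[model.component_index(k)] = v
        expected = (7.0 * init + 7.0 * c_in) / 14.0
        got = traj.states[i_end_feed]
        keep = [i for i, n in enumerate(model.components) if n != "S_O2"]
        np.testing.assert_allclose(got[keep], expected[keep], rtol=1e-6,
                                   atol=1e-8)

    def test_decant_keeps_solubles_and_conserves_particulate_mass(self, inert_model):
        """Ideal supernatant withdrawal: soluble concentrations unchanged,
        particulate mass conserved on the reduced volume."""
        model = inert_model
        sched = _short_schedule(sbr_influent())
        traj = simulate_sbr(model, sched, model.params.defaults,
                            sbr_initial_state(model))
        t_decant_end = sum(p.duration for p in sched.phases[:5])
        i_pre = np.searchsorted(traj.t, t_decant_end) - 1
        i_post = np.searchsorted(traj.t, t_decant_end, side="right")
        pre, post = traj.states[i_pre], traj.states[i_post]
        v_pre, v_post = traj.volume[i_pre], traj.volume[i_post]
        sol = model.soluble_mask.copy()
        sol[0] = False  # DO is a forcing
        np.testing.assert_allclose(post[sol], pre[sol], rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(post[~sol] * v_post, pre[~sol] * v_pre,
                                   rtol=1e-9, atol=1e-9)

    def test_cycle_level_nitrogen_mass_balance(self, model):
        """N in feed + N at start = N at end + N decanted, closed to < 0.5%."""
        sched = sbr_schedule("complete")
        init = sbr_initial_state(model)
        pvec = model.params.defaults
        traj = simulate_sbr(model, sched, pvec, init)
        n_w = model.composition_matrix(pvec)[1]
        influent = sbr_influent()
        c_in = np.zeros(len(model.components))
        for k, v in influent.items():
            c_in[model.component_index(k)] = v
        n_in = 7.0 * (n_w @ c_in)
        n_start = sched.volume0 * (n_w @ init)
        n_end = traj.volume[-1] * (n_w @ traj.states[-1])
        # decanted supernatant: soluble fraction of the pre-decant state
        t_dec = sum(p.duration for p in sched.phases[:5])
        i_pre = np.searchsorted(traj.t, t_dec) - 1
        sol = model.soluble_mask
        n_dec = 7.0 * (n_w[sol] @ traj.states[i_pre][sol])
        imbalance = abs((n_start + n_in) - (n_end + n_dec)) / (n_start + n_in)
        assert imbalance < 0.005

    def test_volume_bookkeeping_invariant_over_cycles(self, model):
        sched = sbr_schedule("complete")
        traj = simulate_sbr(model, sched, model.params.defaults,
                            sbr_initial_state(model), n_cycles=2)
        assert traj.volume[0] == pytest.approx(7.0)
        assert traj.volume[-1] == pytest.approx(7.0)
        assert traj.volume.max() == pytest.approx(14.0)

    def test_unbalanced_schedule_rejected(self):
        with pytest.raises(ValueError, match="volume"):
            SBRSchedule(phases=(
                Phase("feed", 3 * MINUTE, volume=7.0, composition={"S_S": 100.0}),
                Phase("decant", 6 * MINUTE, volume=3.0),
            ), volume0=7.0)

    def test_refinement_convergence(self, model):
        """Halving integrator tolerances barely moves the observables."""
        sched = _short_schedule(sbr_influent())
        init = sbr_initial_state(model)
        pvec = model.params.defaults
        a = simulate_sbr(model, sched, pvec, init, rtol=1e-6, atol=1e-8)
        b = simulate_sbr(model, sched, pvec, init, rtol=5e-7, atol=5e-9)
        scale = np.abs(a.observables).max(axis=1, keepdims=True)
        rel = np.abs(a.observables - b.observables) / scale
        assert rel.max() < 1e-4


class TestCSTR:
    def test_inert_tracer_reaches_influent_concentration(self, inert_model):
        """Washout closed form: C(t) = Cin (1 - exp(-t/HRT)); ~Cin by 5 HRT."""
        model = inert_model
        cfg = CSTRConfig(volume=4.0, flow=8.0, srt=12.0,
                         influent={"S_I": 100.0}, do=0.0)
        init = np.zeros(len(model.components))
        hrt = cfg.volume / cfg.flow
        traj = simulate_cstr(model, cfg, model.params.defaults, init,
                             duration=5 * hrt, dt_out=hrt / 50)
        si = traj.component("S_I")
        assert abs(si[-1] - 100.0 * (1 - np.exp(-5.0))) / 100.0 < 1e-3
        assert abs(si[-1] - 100.0) / 100.0 < 0.01
        # closed-form exponential approach along the way
        expected = 100.0 * (1 - np.exp(-traj.t / hrt))
        np.testing.assert_allclose(si, expected, atol=0.1)

    def test_slow_growers_wash_out(self, model):
        """Effective growth below 1/SRT: the nitrifier pool decays toward zero."""
        cfg = cstr_config()
        cfg = CSTRConfig(volume=cfg.volume, flow=cfg.flow, srt=cfg.srt,
                         influent=cfg.influent, do=0.02)  # DO-starved AOB
        init = cstr_initial_state(model)
        traj = simulate_cstr(model, cfg, model.params.defaults, init,
                             duration=60.0, dt_out=0.5)
        x_aob = traj.component("X_AOB")
        assert x_aob[-1] < 0.05 * x_aob[0]

    def test_matches_tighter_tolerance_rerun(self, model):
        """Trajectory agrees with a 10x tighter re-run to < 1e-4 relative."""
        cfg = cstr_config()
        init = cstr_initial_state(model)
        pvec = model.params.defaults
        a = simulate_cstr(model, cfg, pvec, init, duration=5.0)
        b = simulate_cstr(model, cfg, pvec, init, duration=5.0,
                          rtol=1e-7, atol=1e-9)
        scale = np.abs(b.observables).max(axis=1, keepdims=True)
        assert (np.abs(a.observables - b.observables) / scale).max() < 1e-4

    def test_forcing_shorter_than_duration_rejected(self, model):
        cfg = CSTRConfig(volume=4.0, flow=8.0, srt=12.0,
                         influent={"S_I": 10.0},
                         do=Forcing([0.0, 1.0, 2.0], [0.5, 0.5, 0.5]))
        with pytest.raises(ValueError, match="forcing"):
            simulate_cstr(model, cfg, model.params.defaults,
                          np.zeros(len(model.components)), duration=10.0)


@pytest.fixture(scope="module")
def observe_traj(model):
    sched = _short_schedule(sbr_influent())
    return simulate_sbr(model, sched, model.params.defaults,
                        sbr_initial_state(model))


class TestObserve:
    @pytest.fixture()
    def traj(self, observe_traj):
        return observe_traj

    def test_grid_times_return_exact_grid_values(self, traj):
        ds = observe(traj, traj.t[::7])
        for i, name in enumerate(traj.observable_names):
            np.testing.assert_array_equal(ds.values(name),
                                          traj.observables[i, ::7])

    def test_midpoint_is_arithmetic_mean(self, traj):
        t_mid = 0.5 * (traj.t[3] + traj.t[4])
        ds = observe(traj, [t_mid])
        for i, name in enumerate(traj.observable_names):
            mean = 0.5 * (traj.observables[i, 3] + traj.observables[i, 4])
            assert ds.values(name)[0] == pytest.approx(mean, rel=1e-12)

    def test_dense_resample_roundtrip(self, traj):
        """Dense resampling then re-observation at original times round-trips."""
        from asmcal.scenarios import Trajectory

        dense_t = np.linspace(traj.t[0], traj.t[-1], 4 * len(traj.t))
        dense_t = np.unique(np.concatenate([dense_t, traj.t]))
        dense_obs = np.vstack([np.interp(dense_t, traj.t, traj.observables[i])
                               for i in range(4)])
        dense = Trajectory(t=dense_t,
                           states=np.zeros((len(dense_t), len(traj.components))),
                           volume=np.ones_like(dense_t),
                           components=traj.components,
                           observables=dense_obs)
        ds = observe(dense, traj.t)
        for i, name in enumerate(traj.observable_names):
            np.testing.assert_allclose(ds.values(name), traj.observables[i],
                                       atol=1e-8)

    def test_extrapolation_rejected(self, traj):
        with pytest.raises(ValueError, match="span"):
            observe(traj, [traj.t[-1] + 1.0])
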