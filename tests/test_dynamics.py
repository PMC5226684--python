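import numpy as np
import pytest
from scipy.linalg import expm

from wormdmd.connectome import Connectome, conductance_matrices
from wormdmd import dynamics as dyn


def _lone_neuron(params=None):
    c = Connectome(["A"], np.zeros((1, 1), dtype=int), np.zeros((1, 1), dtype=int),
                   np.array(["E"], dtype=object))
    cond = conductance_matrices(c, 100.0)
    params = (params or dyn.ModelParams()).with_thresholds(cond)
    return cond, params


def _gap_pair(count=3):
    gap = np.array([[0, count], [count, 0]])
    c = Connectome(["A", "B"], np.zeros((2, 2), dtype=int), gap,
                   np.array(["E", "E"], dtype=object))
    cond = conductance_matrices(c, 100.0)
    return cond, dyn.ModelParams().with_thresholds(cond)


class TestSigmoid:
    def test_half_activation_at_threshold(self):
        assert dyn.sigmoid(-20.0, 0.125, -20.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("v,expected", [(1e6, 1.0), (-1e6, 0.0)])
    def test_saturates_without_overflow(self, v, expected):
        assert dyn.sigmoid(v, 0.125, 0.0) == pytest.approx(expected)

    def test_zero_slope_gives_half_everywhere(self):
        v = np.linspace(-100, 100, 7)
        np.testing.assert_allclose(dyn.sigmoid(v, 0.0, -20.0), 0.5)

    def test_monotone_increasing(self):
        v = np.linspace(-80, 40, 200)
        phi = dyn.sigmoid(v, 0.125, -20.0)
        assert (np.diff(phi) > 0).all()


class TestSynapticEquilibrium:
    def test_at_threshold_with_default_rates(self):
        """With ar=1/s, ad=5/s and phi=1/2, s_eq = 0.5/(0.5+5) = 1/11."""
        p = dyn.ModelParams(vth=np.array([-20.0]))
        assert dyn.synaptic_equilibrium(np.array([-20.0]), p)[0] == pytest.approx(1 / 11)

    def test_vanishes_far_below_threshold(self):
        p = dyn.ModelParams(vth=np.array([0.0]))
        assert dyn.synaptic_equilibrium(np.array([-500.0]), p)[0] == pytest.approx(0.0, abs=1e-12)

    def test_slow_decay_limit_saturates(self):
        p = dyn.ModelParams(ad=1e-9, vth=np.array([0.0]))
        assert dyn.synaptic_equilibrium(np.array([0.0]), p)[0] == pytest.approx(1.0, rel=1e-6)


class TestVectorField:
    def test_leak_equilibrium_of_isolated_neuron(self):
        cond, params = _lone_neuron()
        state = dyn.NetworkState(np.array([params.Ecell]),
                                 dyn.synaptic_equilibrium(np.array([params.Ecell]), params))
        deriv = dyn.vector_field(state, cond, params)
        assert abs(deriv.v[0]) < 1e-12 and abs(deriv.s[0]) < 1e-12

    def test_gap_currents_conserve_charge_pairwise(self, small_net, rng):
        _, cond, params, _ = small_net
        state = dyn.NetworkState(rng.uniform(-60, 0, cond.n), rng.uniform(0, 1, cond.n))
        assert abs(dyn.gap_currents(state, cond).sum()) < 1e-9

    def test_single_synapse_current_term(self):
        """G=300 pS, s=0.5, v_post=-40 mV, E=0 mV -> drive of +6000 units."""
        syn = np.array([[0, 3], [0, 0]])
        c = Connectome(["post", "pre"], syn, np.zeros((2, 2), dtype=int),
                       np.array(["E", "E"], dtype=object))
        cond = conductance_matrices(c, 100.0)
        params = dyn.ModelParams(Gc=0.0, vth=np.zeros(2))
        state = dyn.NetworkState(np.array([-40.0, 0.0]), np.array([0.0, 0.5]))
        deriv = dyn.vector_field(state, cond, params)
        # I_syn = 300 * 0.5 * (v_i - E_j) = -6000; enters vdot with opposite sign
        assert deriv.v[0] * params.C == pytest.approx(6000.0)

    def test_nonfinite_state_is_hard_error(self, small_net):
        _, cond, params, _ = small_net
        state = dyn.NetworkState(np.full(cond.n, np.nan), np.zeros(cond.n))
        with pytest.raises(dyn.SimulationBlowupError):
            dyn.vector_field(state, cond, params)


class TestFixedPoint:
    def test_decoupled_network_rests_at_leak_reversal(self):
        c = Connectome(["A", "B"], np.zeros((2, 2), dtype=int),
                       np.zeros((2, 2), dtype=int), np.array(["E", "I"], dtype=object))
        cond = conductance_matrices(c, 100.0)
        params = dyn.ModelParams().with_thresholds(cond)
        fp = dyn.find_fixed_point(cond, params)
        np.testing.assert_allclose(fp.v, params.Ecell, atol=1e-9)

    def test_residual_below_tolerance(self, small_net):
        _, cond, params, fp = small_net
        deriv = dyn.vector_field(fp, cond, params)
        assert np.abs(deriv.v).max() < 1e-9 and np.abs(deriv.s).max() < 1e-9

    def test_stable_under_zero_input(self, small_net):
        _, cond, params, fp = small_net
        trace = dyn.integrate(fp, cond, params, dyn.Stimulus.none(cond.n),
                              T=0.1, h=1e-5, dt_record=1e-3)
        drift = np.abs(trace.V - fp.v[:, None]).max()
        assert drift < 1e-6

    def test_unique_across_random_initializations(self, small_net, rng):
        _, cond, params, fp = small_net
        for _ in range(10):
            v0 = fp.v + rng.uniform(-5, 5, cond.n)
            other = dyn.find_fixed_point(cond, params, v0=v0)
            np.testing.assert_allclose(other.v, fp.v, atol=1e-6)

    def test_all_excitatory_voltages_in_reversal_bounding_box(self):
        from wormdmd.synthetic import surrogate_connectome
        c = surrogate_connectome(n=30, n_syn=200, n_gap=30, n_bclass=6,
                                 ei_fraction=1.0, seed=3)
        cond = conductance_matrices(c, 100.0)
        params = dyn.ModelParams().with_thresholds(cond)
        fp = dyn.find_fixed_point(cond, params)
        lo, hi = min(params.Ecell, params.E_exc), max(params.Ecell, params.E_exc)
        assert (fp.v >= lo - 1e-9).all() and (fp.v <= hi + 1e-9).all()


class TestIntegrate:
    def test_leak_decay_matches_closed_form(self):
        """Single leaky neuron: v(t) = Ecell + (v0-Ecell) exp(-Gc t / C)."""
        cond, params = _lone_neuron()
        v0 = params.Ecell + 10.0
        state = dyn.NetworkState(np.array([v0]),
                                 dyn.synaptic_equilibrium(np.array([v0]), params))
        trace = dyn.integrate(state, cond, params, dyn.Stimulus.none(1),
                              T=0.02, h=1e-6, dt_record=1e-4)
        expected = params.Ecell + (v0 - params.Ecell) * np.exp(
            -params.Gc * trace.times / params.C)
        rel = np.abs(trace.V[0] - expected) / 10.0
        assert rel.max() < 1e-3

    def test_euler_error_halves_with_step(self):
        """Gap-coupled pair is linear in v: error vs matrix exponential ~ O(h)."""
        cond, params = _gap_pair()
        v0 = np.array([-30.0, -45.0])
        s0 = dyn.synaptic_equilibrium(v0, params)
        A = -(params.Gc * np.eye(2) + np.diag(cond.G_gap.sum(1)) - cond.G_gap) / params.C

        def exact(t):
            return params.Ecell + expm(A * t) @ (v0 - params.Ecell)

        errs = []
        for h in (2e-5, 1e-5):
            tr = dyn.integrate(dyn.NetworkState(v0, s0), cond, params,
                               dyn.Stimulus.none(2), T=0.01, h=h, dt_record=2e-3)
            errs.append(max(np.abs(tr.V[:, k] - exact(t)).max()
                            for k, t in enumerate(tr.times)))
        ratio = errs[0] / errs[1]
        assert 1.6 < ratio < 2.4

    def test_thirty_steps_per_recorded_column(self, small_net):
        _, cond, params, fp = small_net
        trace = dyn.integrate(fp, cond, params, dyn.Stimulus.none(cond.n),
                              T=0.003, h=1e-6, dt_record=3e-5)
        assert trace.dt_record / 1e-6 == pytest.approx(30)
        assert trace.m == 101  # T/dt_record + 1 columns

    def test_record_interval_must_divide_step(self, small_net):
        _, cond, params, fp = small_net
        with pytest.raises(ValueError, match="integer multiple"):
            dyn.integrate(fp, cond, params, dyn.Stimulus.none(cond.n),
                          T=0.01, h=3e-6, dt_record=1e-5)

    def test_synaptic_activity_stays_in_unit_interval(self, small_net, rng):
        _, cond, params, fp = small_net
        state = dyn.NetworkState(fp.v + rng.uniform(-20, 20, cond.n),
                                 rng.uniform(0, 1, cond.n))
        v, s = state.v.copy(), state.s.copy()
        for _ in range(500):
            deriv = dyn.vector_field(dyn.NetworkState(v, s), cond, params)
            v += 1e-5 * deriv.v
            s = np.clip(s + 1e-5 * deriv.s, 0, 1)
            assert (s >= 0).all() and (s <= 1).all()

    def test_blowup_detection_reports_time(self, small_net):
        _, cond, params, fp = small_net
        huge = dyn.Stimulus.constant(np.full(cond.n, 1e12))
        with pytest.raises(dyn.SimulationBlowupError, match="t ="):
            dyn.integrate(fp, cond, params, huge, T=0.01, h=1e-5, dt_record=1e-4)


class TestStimuli:
    def test_impulse_norm_and_support(self):
        stim = dyn.random_impulse(50, seed=1, amplitude=10.0, duration=1e-5)
        assert np.linalg.norm(stim.current(0.0)) == pytest.approx(10.0)
        assert np.linalg.norm(stim.current(5e-6)) == pytest.approx(10.0)
        assert not stim.current(1e-5 + 1e-12).any()

    def test_impulse_deterministic_given_seed(self):
        a = dyn.random_impulse(50, seed=9).current(0.0)
        b = dyn.random_impulse(50, seed=9).current(0.0)
        np.testing.assert_array_equal(a, b)

    def test_drive_supported_on_bclass_only(self, small_net):
        c, *_ = small_net
        stim = dyn.proprioceptive_drive(c, A=30.0, omega=25.0, k=0.886)
        from wormdmd.connectome import bclass_members
        idx = c.index(bclass_members(c))
        mask = np.zeros(c.n, dtype=bool)
        mask[idx] = True
        for t in (0.0, 0.01, 0.3):
            assert not stim.current(t)[~mask].any()

    def test_dorsal_ventral_same_position_opposite_sign(self):
        dv = np.array(["dorsal", "ventral"], dtype=object)
        c = Connectome(["DB1", "VB1"], np.zeros((2, 2), dtype=int),
                       np.zeros((2, 2), dtype=int), np.array(["E", "E"], dtype=object),
                       np.array([0.3, 0.3]), dv)
        stim = dyn.proprioceptive_drive(c, A=30.0, omega=25.0, k=0.886)
        for t in (0.01, 0.07, 0.2):
            a, b = stim.current(t)
            assert a == pytest.approx(-b)

    def test_drive_phase_zero_at_origin(self):
        dv = np.array(["ventral"], dtype=object)
        c = Connectome(["VB1"], np.zeros((1, 1), dtype=int), np.zeros((1, 1), dtype=int),
                       np.array(["E"], dtype=object), np.array([0.0]), dv)
        stim = dyn.proprioceptive_drive(c, A=30.0, omega=25.0, k=0.886)
        assert stim.current(0.0)[0] == pytest.approx(0.0)

    def test_drive_missing_position_is_hard_error(self):
        dv = np.array(["ventral"], dtype=object)
        c = Connectome(["VB1"], np.zeros((1, 1), dtype=int), np.zeros((1, 1), dtype=int),
                       np.array(["E"], dtype=object), None, dv)
        with pytest.raises(ValueError, match="soma position"):
            dyn.proprioceptive_drive(c)

    def test_plm_drive_constant_on_plm_members(self, small_net):
        c, *_ = small_net
        stim = dyn.plm_drive(c, 100.0)
        vec = stim.current(0.0)
        np.testing.assert_array_equal(vec, stim.current(1.0))
        support = {c.neuron_ids[i] for i in np.flatnonzero(vec)}
        assert support == {"PLML", "PLMR"}

    def test_plm_absent_is_hard_error(self):
        c = Connectome(["A"], np.zeros((1, 1), dtype=int), np.zeros((1, 1), dtype=int),
                       np.array(["E"], dtype=object))
        with pytest.raises(ValueError, match="PLM"):
            dyn.plm_drive(c, 1.0)
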