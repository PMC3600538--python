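import numpy as np
import pytest

import neurosim as ns


def passive_step_protocol(dt, t_stop, amp):
    return ns.StimulusProtocol(dt=dt, t_stop=t_stop, delay=0.0,
                               duration=t_stop, amp0=amp, n_sweeps=1)


class TestInitState:
    def test_gates_start_at_steady_state(self, fork_small, passive_params):
        st = ns.init_state(fork_small, passive_params, v0=-65.0)
        m_inf, h_inf, n_inf = ns.gate_steady_state(-65.0)
        assert np.allclose(st.gates.m, m_inf)
        assert np.allclose(st.gates.h, h_inf)
        assert np.allclose(st.gates.n, n_inf)
        assert np.all(st.v == -65.0)

    def test_near_equilibrium_hh_soma_barely_drifts(self):
        """Steady-state initialization at -65 mV is close to the true HH
        resting point; 100 unstimulated steps must drift < 1 mV."""
        m = ns.make_cable(1)  # hh soma
        p = ns.BiophysParams()
        sim = ns.Simulator(m, p)
        st = sim.init_state(-65.0)
        for _ in range(100):
            st = sim.step(st, np.zeros(1), 0.1)
        assert abs(st.v[0] - (-65.0)) < 1.0


class TestStep:
    def test_passive_fixed_point(self, single_compartment):
        m, p, G, C = single_compartment
        sim = ns.Simulator(m, p)
        st = sim.init_state(p.e_pas)
        st = sim.step(st, np.zeros(1), 0.1)
        assert st.v[0] == pytest.approx(p.e_pas, rel=1e-14)
        assert st.t == pytest.approx(0.1)

    def test_constant_current_follows_closed_form_recurrence(self, single_compartment):
        """v_{n+1} = (C/dt v_n + G e + I) / (C/dt + G), iterated by hand."""
        m, p, G, C = single_compartment
        I, dt = 0.5, 0.1
        sim = ns.Simulator(m, p)
        st = sim.init_state(p.e_pas)
        v_ref = p.e_pas
        for _ in range(50):
            st = sim.step(st, np.full(1, I), dt)
            v_ref = (C / dt * v_ref + G * p.e_pas + I) / (C / dt + G)
            assert st.v[0] == pytest.approx(v_ref, rel=1e-12)

    @pytest.mark.parametrize("dt", [0.01, 0.1, 1.0, 10.0])
    def test_unconditional_stability_any_dt(self, single_compartment, dt):
        m, p, G, C = single_compartment
        I = 0.3
        sim = ns.Simulator(m, p)
        st = sim.init_state(p.e_pas)
        for _ in range(int(200 / dt)):
            st = sim.step(st, np.full(1, I), dt)
            assert abs(st.v[0]) < 200
        assert st.v[0] == pytest.approx(p.e_pas + I / G, rel=1e-6)

    def test_skip_solve_freezes_voltage(self, fork_small):
        p = ns.BiophysParams()
        sim = ns.Simulator(fork_small, p, skip_solve=True)
        st = sim.init_state()
        st2 = sim.step(st, np.zeros(fork_small.n_segments), 0.1)
        assert np.array_equal(st2.v, st.v)


class TestRunSweep:
    def test_zero_amplitude_passive_cell_stays_flat(self):
        m = ns.make_cable(4, mech="pas")
        p = ns.BiophysParams()
        proto = passive_step_protocol(0.1, 20.0, 0.0)
        tr = ns.run_sweep(m, p, proto, v0=p.e_pas)
        assert np.allclose(tr, p.e_pas, atol=1e-10)

    def test_hyperpolarizing_step_charges_monotonically(self, single_compartment):
        m, p, G, _ = single_compartment
        proto = passive_step_protocol(0.1, 30.0, -1.0)
        tr = ns.run_sweep(m, p, proto, v0=p.e_pas)
        assert np.all(np.diff(tr) <= 1e-12)
        assert tr[-1] == pytest.approx(p.e_pas - 1.0 / G, rel=1e-4)

    def test_first_order_convergence_to_analytic_charging_curve(self, single_compartment):
        """Backward Euler is O(dt): the max deviation from
        v(t) = e + (I/G)(1 - exp(-t/tau)) shrinks ~10x from dt=0.1 to 0.01."""
        m, p, G, C = single_compartment
        tau, I = C / G, 0.1
        err = {}
        for dt in (0.1, 0.01):
            proto = passive_step_protocol(dt, 10.0, I)
            tr = ns.run_sweep(m, p, proto, v0=p.e_pas)
            t = np.arange(proto.n_samples) * dt
            analytic = p.e_pas + (I / G) * (1 - np.exp(-t / tau))
            err[dt] = np.abs(tr - analytic).max()
        assert 5 < err[0.1] / err[0.01] < 20

    def test_spike_train_at_one_nA_with_hot_soma(self, fork_small):
        p = ns.soma_dendrite_params(fork_small)
        proto = ns.StimulusProtocol(dt=0.01, t_stop=50.0, delay=5.0,
                                    duration=40.0, amp0=1.0)
        tr = ns.run_sweep(fork_small, p, proto)
        assert len(ns.detect_spikes(tr, proto.dt)) >= 2

    def test_out_of_range_record_segment_rejected(self, fork_small, passive_params):
        proto = ns.StimulusProtocol(record_segment=999, t_stop=20, delay=0,
                                    duration=10)
        with pytest.raises(ValueError, match="out of range"):
            ns.run_sweep(fork_small, passive_params, proto)

    @pytest.mark.parametrize("solver", ns.SOLVERS)
    def test_solver_choice_does_not_change_traces(self, fork_small, solver):
        p = ns.soma_dendrite_params(fork_small)
        proto = ns.StimulusProtocol(dt=0.1, t_stop=20.0, delay=2.0,
                                    duration=15.0, amp0=1.0)
        ref = ns.run_sweep(fork_small, p, proto, solver="serial")
        tr = ns.run_sweep(fork_small, p, proto, solver=solver)
        assert np.abs(tr - ref).max() < 1e-6

    def test_voltage_bounded_for_protocol_amplitude_range(self):
        m = ns.make_fork_total(320)
        p = ns.soma_dendrite_params(m)
        for amp in (-2.0, -0.5, 1.0, 3.0):
            proto = ns.StimulusProtocol(dt=0.1, t_stop=40.0, delay=2.0,
                                        duration=30.0, amp0=amp)
            tr = ns.run_sweep(m, p, proto)
            assert np.all(np.isfinite(tr))
            assert tr.min() > -200 and tr.max() < 200


class TestProtocolAndPopulation:
    def test_thirteen_sweep_amplitude_ladder(self):
        proto = ns.StimulusProtocol(n_sweeps=13)
        assert np.allclose(proto.amplitudes,
                           np.arange(-1.0, 2.61, 0.3), atol=1e-12)
        assert proto.amplitudes[-1] == pytest.approx(2.6)

    def test_single_sweep_protocol_reduces_to_run_sweep(self, fork_small):
        p = ns.BiophysParams()
        proto = ns.StimulusProtocol(dt=0.1, t_stop=20, delay=2, duration=10)
        ts = ns.run_protocol(fork_small, p, proto)
        assert ts.voltages.shape == (1, proto.n_samples)
        assert np.array_equal(ts.voltages[0], ns.run_sweep(fork_small, p, proto))

    def test_sweep_execution_order_is_irrelevant(self, fork_small):
        """Sweeps are independent: each row equals the standalone run of
        that sweep, regardless of execution order."""
        p = ns.soma_dendrite_params(fork_small)
        proto = ns.StimulusProtocol(dt=0.1, t_stop=20, delay=2, duration=10,
                                    n_sweeps=5)
        ts = ns.run_protocol(fork_small, p, proto)
        for k in reversed(range(proto.n_sweeps)):
            alone = ns.run_sweep(fork_small, p, proto, sweep_index=k)
            assert np.array_equal(ts.voltages[k], alone)

    def test_population_of_identical_cells_is_deterministic(self):
        m = ns.make_fork(3, 2)
        p = ns.BiophysParams()
        proto = ns.StimulusProtocol(dt=0.1, t_stop=10, delay=1, duration=5,
                                    n_sweeps=2)
        sets = ns.run_population([(m, p)] * 5, proto)
        for ts in sets[1:]:
            assert np.array_equal(ts.voltages, sets[0].voltages)

    def test_mixed_population_equals_standalone_runs(self):
        cells = [(ns.make_fork(4, 2), ns.BiophysParams()),
                 (ns.make_binary_tree(3), ns.BiophysParams()),
                 (ns.make_cable(6), ns.soma_dendrite_params(ns.make_cable(6)))]
        proto = ns.StimulusProtocol(dt=0.1, t_stop=10, delay=1, duration=5,
                                    n_sweeps=2)
        batch = ns.run_population(cells, proto)
        for (m, p), ts in zip(cells, batch):
            alone = ns.run_protocol(m, p, proto)
            assert np.array_equal(ts.voltages, alone.voltages)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            ns.run_population([], ns.StimulusProtocol())


class TestPrecision:
    def test_single_precision_runs_in_float32(self, fork_small):
        p = ns.BiophysParams()
        proto = ns.StimulusProtocol(dt=0.1, t_stop=10, delay=1, duration=5)
        tr = ns.run_sweep(fork_small, p, proto, precision="single")
        assert tr.dtype == np.float32

    def test_single_close_to_double_on_passive_run(self, fork_small):
        p = ns.BiophysParams()
        proto = ns.StimulusProtocol(dt=0.1, t_stop=50, delay=5, duration=40,
                                    amp0=-1.0)
        lo = ns.run_sweep(fork_small, p, proto, precision="single")
        hi = ns.run_sweep(fork_small, p, proto, precision="double")
        assert np.abs(lo.astype(np.float64) - hi).max() < 0.05

    def test_unknown_precision_rejected(self, fork_small):
        with pytest.raises(ValueError, match="precision"):
            ns.Simulator(fork_small, ns.BiophysParams(), precision="half")
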