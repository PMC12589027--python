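import numpy as np
import pytest

from critsnn import NeuronParams, ProtocolConfig, build_network, preset_stdp
from critsnn.engine import (
    StimulusPattern,
    make_patterns,
    measure_evoked_trials,
    run_free,
    run_repetitive_stimulation,
    run_spontaneous_with_monitoring,
)
from critsnn.model import (
    deliver_due_events,
    draw_spikes,
    fire_and_deliver,
    step_subthreshold,
)
from critsnn.plasticity import PlasticityTraces, on_spike_update

from conftest import make_state


class TestBuildNetwork:
    def test_default_sizes(self, nparams):
        st = build_network(ProtocolConfig(), nparams)
        assert st.n == 100
        assert st.n_exc == 80 and st.n_inh == 20
        assert np.all(st.w == 0)
        # all-to-all minus self-connections
        assert st.w.size - st.n == 9900

    def test_tiny_synapse_count(self, nparams):
        st = build_network(ProtocolConfig(n_exc=2, n_inh=1), nparams)
        assert st.n * (st.n - 1) == 6

    def test_seed_determinism(self, nparams):
        a = build_network(ProtocolConfig(init_seed=5), nparams)
        b = build_network(ProtocolConfig(init_seed=5), nparams)
        c = build_network(ProtocolConfig(init_seed=6), nparams)
        assert np.array_equal(a.v, b.v)
        assert not np.array_equal(a.v, c.v)

    def test_initial_v_in_range(self, nparams):
        st = build_network(ProtocolConfig(), nparams)
        assert np.all((st.v >= nparams.v_rest) & (st.v <= nparams.v_th))


class TestMakePatterns:
    def test_disjoint_across_patterns(self, nparams):
        st = build_network(ProtocolConfig(), nparams)
        pats = make_patterns(st, 4, 6, rng=np.random.default_rng(0))
        all_targets = [t for p in pats for t in p.targets]
        assert len(all_targets) == 24
        assert len(set(all_targets)) == 24
        assert all(st.is_exc[list(p.targets)].all() for p in pats)

    def test_insufficient_units(self, nparams):
        st = make_state(n_exc=5, n_inh=2)
        with pytest.raises(ValueError, match="excitatory"):
            make_patterns(st, 2, 4)

    def test_zero_size_rejected(self, nparams):
        st = make_state()
        with pytest.raises(ValueError):
            make_patterns(st, 1, 0)


class TestRunFree:
    def test_zero_duration(self, stdp):
        st = make_state()
        h0 = st.state_hash()
        res = run_free(st, stdp, 0.0)
        assert len(res.spikes) == 0
        assert st.state_hash() == h0

    def test_seed_determinism(self, nparams, stdp):
        out = []
        for _ in range(2):
            st = make_state(n_exc=8, n_inh=2, noise_seed=11)
            r = run_free(st, stdp, 3.0)
            out.append(r)
        assert np.array_equal(out[0].spikes.times, out[1].spikes.times)
        assert np.array_equal(out[0].spikes.units, out[1].spikes.units)

    def test_jit_matches_python_fallback(self, nparams, stdp):
        results = []
        for use_jit in (True, False):
            st = make_state(n_exc=8, n_inh=2, noise_seed=5)
            st.w[:] = 0.4
            np.fill_diagonal(st.w, 0.0)
            r = run_free(st, stdp, 2.0, use_jit=use_jit,
                         record_currents=True)
            results.append((r, st))
        (ra, sa), (rb, sb) = results
        assert np.array_equal(ra.spikes.times, rb.spikes.times)
        assert np.array_equal(ra.spikes.units, rb.spikes.units)
        assert np.array_equal(sa.w, sb.w)
        assert np.array_equal(sa.v, sb.v)
        assert np.array_equal(ra.currents.E, rb.currents.E)

    def test_matches_reference_step_operations(self, nparams, stdp):
        """The chunked kernel reproduces the fine-grained ops exactly."""
        st_k = make_state(n_exc=4, n_inh=2, noise_seed=9)
        st_r = st_k.clone(np.random.default_rng(123))
        st_k.rng = np.random.default_rng(123)
        st_k.w[:] = 0.6
        st_r.w[:] = 0.6
        np.fill_diagonal(st_k.w, 0.0)
        np.fill_diagonal(st_r.w, 0.0)

        res = run_free(st_k, stdp, 1.5, plasticity=False, use_jit=True)
        ref_spikes = []
        for _ in range(15_000):
            deliver_due_events(st_r)
            step_subthreshold(st_r, nparams)
            ids = draw_spikes(st_r, nparams)
            fire_and_deliver(st_r, ids, nparams)
            ref_spikes.extend((st_r.step, int(i)) for i in ids)
        kernel_spikes = list(zip(
            np.round(res.spikes.times / (nparams.dt / 1000.0)).astype(int),
            res.spikes.units))
        assert kernel_spikes == ref_spikes
        assert np.allclose(st_r.v, st_k.v, atol=1e-12)
        assert np.allclose(st_r.g_exc, st_k.g_exc, atol=1e-12)
        assert np.allclose(st_r.x, st_k.x, atol=1e-12)

    def test_kernel_stdp_matches_event_replay(self, stdp):
        """Matrix STDP equals per-synapse all-to-all event updates."""
        # boost the noise rate to get a dense spike record
        p = NeuronParams(f_rest=20.0)
        st = make_state(n_exc=4, n_inh=2, noise_seed=2, params=p)
        st.w[:] = 0.5
        np.fill_diagonal(st.w, 0.0)
        res = run_free(st, stdp, 2.0, plasticity=True)
        assert len(res.spikes) > 50

        steps = np.round(res.spikes.times / (p.dt / 1000.0)).astype(int)
        order = np.lexsort((res.spikes.units, steps))
        steps, units = steps[order], res.spikes.units[order]
        n = st.n
        w = np.full((n, n), 0.5)
        np.fill_diagonal(w, 0.0)
        traces = {(a, b): PlasticityTraces()
                  for a in range(n) for b in range(n) if a != b}
        # replay in the engine's order: spikes sorted by (step, unit),
        # each spike acting first as presynaptic then as postsynaptic
        for step, u in zip(steps, units):
            t_ms = step * p.dt
            for b in range(n):  # u as presynaptic unit
                if b != u:
                    w[u, b] = on_spike_update(
                        w[u, b], (t_ms, "pre"), traces[(u, b)], stdp,
                        bool(st.is_exc[u]))
            for a in range(n):  # u as postsynaptic unit
                if a != u:
                    w[a, u] = on_spike_update(
                        w[a, u], (t_ms, "post"), traces[(a, u)], stdp,
                        bool(st.is_exc[a]))
        assert np.allclose(w, st.w, atol=1e-9)

    def test_weight_snapshots(self, stdp):
        st = make_state(n_exc=8, n_inh=2)
        res = run_free(st, stdp, 2.0, weight_snapshot_stride_s=1.0)
        assert len(res.weight_snapshots) == 3  # t = 0, 1, 2
        assert res.weight_snapshots[0][0] == 0.0

    def test_current_recording_shape(self, stdp):
        st = make_state(n_exc=3, n_inh=2)
        res = run_free(st, stdp, 0.5, record_currents=True)
        assert res.currents.E.shape == (5, 5000)
        assert np.all(res.currents.E >= 0)
        assert np.all(res.currents.I <= 0)


class TestRepetitiveStimulation:
    def test_balanced_order_and_timing(self, stdp):
        st = make_state(n_exc=8, n_inh=2, noise_seed=1)
        pats = make_patterns(st, 2, 2, rng=np.random.default_rng(0))
        log, spikes = run_repetitive_stimulation(st, pats, stdp,
                                                 n_repeats=5, rate_hz=1.0)
        assert len(log) == 10
        times = [t for t, _ in log]
        assert times == pytest.approx(list(range(10)))
        ids = [pid for _, pid in log]
        assert ids.count("P0") == 5 and ids.count("P1") == 5

    def test_single_pattern_schedule(self, stdp):
        st = make_state(n_exc=4, n_inh=1, noise_seed=2)
        pats = [StimulusPattern(id="P0", targets=(0, 1))]
        log, _ = run_repetitive_stimulation(st, pats, stdp, n_repeats=5)
        assert [t for t, _ in log] == pytest.approx([0, 1, 2, 3, 4])

    def test_order_determinism(self, stdp):
        orders = []
        for _ in range(2):
            st = make_state(n_exc=8, n_inh=2, noise_seed=4)
            pats = make_patterns(st, 3, 2, rng=np.random.default_rng(1))
            log, _ = run_repetitive_stimulation(st, pats, stdp, n_repeats=4)
            orders.append([pid for _, pid in log])
        assert orders[0] == orders[1]

    def test_empty_patterns_rejected(self, stdp):
        st = make_state()
        with pytest.raises(ValueError):
            run_repetitive_stimulation(st, [], stdp)


class TestMonitoring:
    def test_window_layout(self, stdp):
        st = make_state(n_exc=4, n_inh=1, noise_seed=3)
        wins = run_spontaneous_with_monitoring(
            st, stdp, duration_h=2.0 / 60.0, monitor_every_h=1.0 / 60.0,
            monitor_min=0.5, current_window_s=2.0)
        assert len(wins) == 2
        assert wins[0].t_start_s == 0.0
        assert wins[1].t_start_s == 60.0
        assert wins[0].currents.duration_s == pytest.approx(2.0)

    def test_overlong_window_rejected(self, stdp):
        st = make_state()
        with pytest.raises(ValueError):
            run_spontaneous_with_monitoring(
                st, stdp, 1.0, monitor_every_h=0.1, monitor_min=30.0)


class TestEvokedTrials:
    def test_trial_layout_and_base_state_untouched(self, stdp):
        st = make_state(n_exc=8, n_inh=2, noise_seed=6)
        pats = make_patterns(st, 2, 2, rng=np.random.default_rng(2))
        h0 = st.state_hash()
        trials = measure_evoked_trials(st, pats, stdp, n_trials=3,
                                       pre_run_s=0.5, window_s=0.3)
        assert st.state_hash() == h0
        assert len(trials) == 6
        labels, counts = np.unique(trials.labels, return_counts=True)
        assert counts.tolist() == [3, 3]
        assert trials.window_s == 0.3
        for tr in trials.trains:
            assert np.all((tr.times >= 0) & (tr.times < 0.3))

    def test_zero_trials(self, stdp):
        st = make_state(n_exc=4, n_inh=1)
        pats = make_patterns(st, 1, 2, rng=np.random.default_rng(0))
        trials = measure_evoked_trials(st, pats, stdp, n_trials=0)
        assert len(trials) == 0

    def test_trial_seed_determinism(self, stdp):
        st = make_state(n_exc=8, n_inh=2, noise_seed=8)
        pats = make_patterns(st, 1, 2, rng=np.random.default_rng(3))
        a = measure_evoked_trials(st, pats, stdp, n_trials=2,
                                  pre_run_s=0.2, window_s=0.2, trial_seed=4)
        b = measure_evoked_trials(st, pats, stdp, n_trials=2,
                                  pre_run_s=0.2, window_s=0.2, trial_seed=4)
        for ta, tb in zip(a.trains, b.trains):
            assert np.array_equal(ta.times, tb.times)
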