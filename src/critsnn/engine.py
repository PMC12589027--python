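"""Network construction and the experimental protocols.

Covers noise-driven development, repetitive patterned stimulation,
spontaneous-activity monitoring and evoked-response trial measurement,
all driven by the chunked kernel in :mod:`critsnn._kernel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .ei_balance import CurrentTraces
from .decoding import TrialSet
from .model import apply_external_stimulus
from .params import NeuronParams, STDPParams
from .state import NetworkState, SpikeTrain

__all__ = [
    "StimulusPattern",
    "ProtocolConfig",
    "FreeRunResult",
    "MonitoringWindow",
    "build_network",
    "make_patterns",
    "run_free",
    "run_repetitive_stimulation",
    "run_spontaneous_with_monitoring",
    "measure_evoked_trials",
]

CHUNK_STEPS = 10_000  # one simulated second at the default dt


@dataclass(frozen=True)
class StimulusPattern:
    """A spatial stimulus: a set of excitatory units depolarised together."""

    id: str
    targets: tuple[int, ...]
    amplitude: float = 30.0  # mV

    def __post_init__(self) -> None:
        if len(self.targets) == 0:
            raise ValueError("stimulus pattern must target at least one unit")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError("duplicate targets in stimulus pattern")


@dataclass
class ProtocolConfig:
    """Sizes, durations and seeds of the full experimental protocol."""

    n_exc: int = 80
    n_inh: int = 20
    development_h: float = 72.0
    n_patterns: int = 4
    pattern_size: int = 6
    stim_amplitude_mv: float = 30.0
    n_repeats: int = 900           # stimuli per pattern
    stim_rate_hz: float = 1.0
    spontaneous_h: float = 12.0
    monitor_every_h: float = 1.0
    monitor_min: float = 10.0
    n_trials: int = 40             # evoked trials per pattern
    pre_trial_s: float = 10.0
    evoked_window_s: float = 1.0
    init_seed: int = 0             # seeds the initial membrane potentials
    noise_seed: int = 1            # seeds the escape-noise stream
    trial_seed: int = 2            # seeds per-trial noise streams

    def __post_init__(self) -> None:
        if self.n_exc <= 0 or self.n_inh < 0:
            raise ValueError("population counts must be positive")
        for name in ("development_h", "spontaneous_h", "monitor_min",
                     "pre_trial_s", "evoked_window_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_repeats < 0 or self.n_trials < 0:
            raise ValueError("counts must be >= 0")
        if self.stim_rate_hz <= 0:
            raise ValueError("stimulation rate must be > 0")


@dataclass
class FreeRunResult:
    spikes: SpikeTrain
    currents: CurrentTraces | None = None
    weight_snapshots: list[tuple[float, np.ndarray]] = field(
        default_factory=list)


@dataclass
class MonitoringWindow:
    t_start_s: float
    spikes: SpikeTrain
    currents: CurrentTraces | None = None


def build_network(config: ProtocolConfig, params: NeuronParams,
                  ) -> NetworkState:
    """Create the fully connected network with all weights at zero.

    Initial membrane potentials are drawn from the dedicated ``init_seed``
    stream; the escape-noise stream is seeded separately with
    ``noise_seed`` so initial conditions and noise can be varied
    independently.
    """
    rng = np.random.default_rng(config.noise_seed)
    init_rng = np.random.default_rng(config.init_seed)
    return NetworkState(config.n_exc, config.n_inh, params, rng,
                        init_rng=init_rng)


def make_patterns(state: NetworkState, n_patterns: int = 4, size: int = 6,
                  rng: np.random.Generator | None = None,
                  amplitude: float = 30.0) -> list[StimulusPattern]:
    """Sample mutually disjoint excitatory target sets without replacement."""
    if size <= 0 or n_patterns <= 0:
        raise ValueError("pattern count and size must be > 0")
    exc_ids = np.flatnonzero(state.is_exc)
    if n_patterns * size > exc_ids.size:
        raise ValueError(
            f"need {n_patterns * size} excitatory units, "
            f"have {exc_ids.size}")
    rng = rng if rng is not None else state.rng
    chosen = rng.choice(exc_ids, size=n_patterns * size, replace=False)
    return [
        StimulusPattern(id=f"P{k}",
                        targets=tuple(int(i) for i in
                                      chosen[k * size:(k + 1) * size]),
                        amplitude=amplitude)
        for k in range(n_patterns)
    ]


def _pending_to_rings(state: NetworkState, n: int):
    ring_exc = np.zeros((_kernel.RING, n))
    ring_inh = np.zeros((_kernel.RING, n))
    for ev in state.pending:
        if ev.deliver_step < state.step \
                or ev.deliver_step >= state.step + _kernel.RING:
            raise ValueError("pending event outside the ring horizon")
        pos = ev.deliver_step % _kernel.RING
        (ring_exc if ev.exc else ring_inh)[pos] += ev.increment
    state.pending = []
    return ring_exc, ring_inh


def _rings_to_pending(state: NetworkState, ring_exc, ring_inh) -> None:
    for pos in range(_kernel.RING):
        ds = state.step + ((pos - state.step) % _kernel.RING)
        if ring_exc[pos].any():
            state.push_event(ds, -1, True, ring_exc[pos].copy())
        if ring_inh[pos].any():
            state.push_event(ds, -1, False, ring_inh[pos].copy())


def run_free(state: NetworkState, stdp: STDPParams, duration_s: float, *,
             plasticity: bool = True, record_currents: bool = False,
             weight_snapshot_stride_s: float | None = None,
             use_jit: bool = True) -> FreeRunResult:
    """Advance the network by ``duration_s`` of noise-driven activity.

    Mutates ``state`` in place and returns the recorded spikes (times in
    seconds relative to the start of this run), optionally dt-resolution
    per-neuron synaptic-current traces and periodic weight snapshots.
    """
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    params = state.params
    n = state.n
    total_steps = int(round(duration_s * 1000.0 / params.dt))
    step0_run = state.step
    fc, ic = _kernel.pack_constants(params, stdp)
    kernel = _kernel.step_chunk_jit if use_jit else _kernel.step_chunk_py
    is_exc_u8 = state.is_exc.astype(np.uint8)

    if record_currents:
        rec_E = np.empty((total_steps, n))
        rec_I = np.empty((total_steps, n))
    else:
        rec_E = np.empty((1, 1))
        rec_I = np.empty((1, 1))

    ring_exc, ring_inh = _pending_to_rings(state, n)
    spike_steps = np.empty(CHUNK_STEPS * n, dtype=np.int64)
    spike_units = np.empty(CHUNK_STEPS * n, dtype=np.int64)
    all_steps: list[np.ndarray] = []
    all_units: list[np.ndarray] = []
    snapshots: list[tuple[float, np.ndarray]] = []
    next_snap = 0.0

    done = 0
    while done < total_steps:
        if weight_snapshot_stride_s is not None \
                and (state.step - step0_run) * params.dt / 1000.0 >= next_snap:
            snapshots.append(((state.step - step0_run) * params.dt / 1000.0,
                              state.w.copy()))
            next_snap += weight_snapshot_stride_s
        S = min(CHUNK_STEPS, total_steps - done)
        u = state.rng.random((S, n))
        n_spk = kernel(
            u, state.step, state.v, state.g_exc, state.g_inh, state.x,
            state.w, state.refractory_until, is_exc_u8,
            state.trace_E, state.trace_I1, state.trace_I2,
            ring_exc, ring_inh, fc, ic, plasticity, record_currents,
            rec_E[done:done + S] if record_currents else rec_E,
            rec_I[done:done + S] if record_currents else rec_I,
            spike_steps, spike_units)
        if n_spk:
            all_steps.append(spike_steps[:n_spk].copy())
            all_units.append(spike_units[:n_spk].copy())
        state.step += S
        done += S
    if weight_snapshot_stride_s is not None:
        snapshots.append(((state.step - step0_run) * params.dt / 1000.0,
                          state.w.copy()))
    _rings_to_pending(state, ring_exc, ring_inh)

    if all_steps:
        steps = np.concatenate(all_steps)
        units = np.concatenate(all_units)
        times = (steps - step0_run) * (params.dt / 1000.0)
        spikes = SpikeTrain(times, units, n, state.is_exc.copy())
    else:
        spikes = SpikeTrain.empty(n, state.is_exc.copy())
    currents = None
    if record_currents:
        currents = CurrentTraces(dt_ms=params.dt, E=rec_E.T.copy(),
                                 I=rec_I.T.copy())
    return FreeRunResult(spikes=spikes, currents=currents,
                         weight_snapshots=snapshots)


def run_repetitive_stimulation(state: NetworkState, patterns, stdp: STDPParams,
                               n_repeats: int = 900, rate_hz: float = 1.0, *,
                               use_jit: bool = True,
                               ) -> tuple[list[tuple[float, str]], SpikeTrain]:
    """Deliver every pattern ``n_repeats`` times in seeded random order.

    The balanced multiset of pattern indices is permuted with the state's
    noise stream; stimuli are applied at the configured constant rate.
    Returns the (time_s, pattern_id) log and the spikes recorded over the
    whole session (times relative to the session start).
    """
    if not patterns:
        raise ValueError("need at least one stimulus pattern")
    interval_s = 1.0 / rate_hz
    params = state.params
    if interval_s * 1000.0 <= max(params.delay_EE, params.delay_other):
        raise ValueError("stimulation interval must exceed synaptic delays")
    order = np.repeat(np.arange(len(patterns)), n_repeats)
    order = state.rng.permutation(order)
    log: list[tuple[float, str]] = []
    spike_parts: list[SpikeTrain] = []
    offsets: list[float] = []
    t0 = 0.0
    for k in order:
        pattern = patterns[int(k)]
        apply_external_stimulus(state, pattern)
        log.append((t0, pattern.id))
        res = run_free(state, stdp, interval_s, plasticity=True,
                       use_jit=use_jit)
        if len(res.spikes):
            spike_parts.append(res.spikes)
            offsets.append(t0)
        t0 += interval_s
    if spike_parts:
        spikes = SpikeTrain.concatenate(spike_parts, offsets)
    else:
        spikes = SpikeTrain.empty(state.n, state.is_exc.copy())
    return log, spikes


def run_spontaneous_with_monitoring(
        state: NetworkState, stdp: STDPParams, duration_h: float, *,
        monitor_every_h: float = 1.0, monitor_min: float = 10.0,
        current_window_s: float = 2.0, use_jit: bool = True,
        ) -> list[MonitoringWindow]:
    """Free-run with periodic monitoring windows.

    Every ``monitor_every_h`` hours a ``monitor_min``-minute window of
    spikes is recorded, with per-neuron synaptic currents captured during
    its first ``current_window_s`` seconds. Activity between windows is
    simulated without recording.
    """
    if monitor_min * 60.0 > monitor_every_h * 3600.0:
        raise ValueError("monitoring window longer than the monitor period")
    n_windows = int(round(duration_h / monitor_every_h))
    windows: list[MonitoringWindow] = []
    t_start = 0.0
    for _ in range(n_windows):
        mon_s = monitor_min * 60.0
        cur_s = min(current_window_s, mon_s)
        res_cur = run_free(state, stdp, cur_s, plasticity=True,
                           record_currents=cur_s > 0, use_jit=use_jit)
        res_rest = run_free(state, stdp, mon_s - cur_s, plasticity=True,
                            use_jit=use_jit)
        spikes = SpikeTrain.concatenate(
            [res_cur.spikes, res_rest.spikes], [0.0, cur_s])
        windows.append(MonitoringWindow(t_start_s=t_start, spikes=spikes,
                                        currents=res_cur.currents))
        gap_s = monitor_every_h * 3600.0 - mon_s
        run_free(state, stdp, gap_s, plasticity=True, use_jit=use_jit)
        t_start += monitor_every_h * 3600.0
    return windows


def measure_evoked_trials(state: NetworkState, patterns, stdp: STDPParams,
                          n_trials: int = 40, *, pre_run_s: float = 10.0,
                          window_s: float = 1.0, trial_seed: int = 2,
                          use_jit: bool = True) -> TrialSet:
    """Record labeled evoked responses without mutating the base state.

    For every pattern x trial the base state is cloned, given a fresh
    per-trial noise stream, free-run for ``pre_run_s`` (so the membrane
    and conductance context varies across trials), then stimulated once;
    spikes in the following ``window_s`` are recorded relative to the
    stimulus. Plasticity is frozen throughout so measurement does not
    itself modify the network.
    """
    labels: list[str] = []
    trains: list[SpikeTrain] = []
    for p_idx, pattern in enumerate(patterns):
        for trial in range(n_trials):
            rng = np.random.default_rng([trial_seed, p_idx, trial])
            st = state.clone(rng)
            run_free(st, stdp, pre_run_s, plasticity=False, use_jit=use_jit)
            apply_external_stimulus(st, pattern)
            res = run_free(st, stdp, window_s, plasticity=False,
                           use_jit=use_jit)
            labels.append(pattern.id)
            trains.append(res.spikes)
    return TrialSet(labels=np.array(labels), trains=trains,
                    n_units=state.n, window_s=window_s)
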