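"""Single-timestep neuron and synapse dynamics (reference implementation).

These operations define the semantics of one simulation step; the
vectorised kernel in :mod:`critsnn._kernel` reproduces them exactly and
is used by the engine for long runs.

Per-step order (fixed by convention, since any order is self-consistent):

1. deliver due pending synaptic events,
2. subthreshold update (Euler step for v, exact exponential decay for
   conductances and resource, trace decay, clock advance),
3. draw spikes from the escape probability,
4. resets, refractoriness, event queueing and resource depletion.
"""

from __future__ import annotations

import math

import numpy as np

from .params import NeuronParams
from .state import NetworkState

__all__ = [
    "escape_spike_prob",
    "deliver_due_events",
    "step_subthreshold",
    "draw_spikes",
    "fire_and_deliver",
    "apply_external_stimulus",
]


def escape_spike_prob(v, params: NeuronParams):
    """Per-step firing probability of the escape-noise rule.

    ``min((Δt/τ)·exp((v − v_th)/b), 1)`` with the prefactor calibrated so
    that a neuron at rest fires at ``f_rest``. Accepts scalars or arrays.
    """
    v = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite membrane potential")
    p = params.escape_prefactor * np.exp((v - params.v_th) / params.b)
    out = np.minimum(p, 1.0)
    return float(out) if out.ndim == 0 else out


def deliver_due_events(state: NetworkState) -> None:
    """Apply every pending synaptic event whose delivery step has come."""
    for ev in state.pop_due_events():
        if ev.exc:
            state.g_exc += ev.increment
        else:
            state.g_inh += ev.increment


def step_subthreshold(state: NetworkState, params: NeuronParams) -> NetworkState:
    """Advance membrane potentials, conductances and resources by dt.

    The membrane potential takes one forward-Euler step of the LIF
    equation using the conductances at the start of the step; refractory
    neurons are held at ``v_rest``. Conductances and the presynaptic
    resource decay by their exact per-step exponential factors, and the
    plasticity traces decay likewise. The clock advances by one step.
    """
    dt = params.dt
    refractory = state.step < state.refractory_until
    dv = (dt / params.tau_m) * (
        (params.v_rest - state.v) * params.g_rest
        + (params.E_exc - state.v) * state.g_exc
        + (params.E_inh - state.v) * state.g_inh
    )
    state.v = state.v + dv
    state.v[refractory] = params.v_rest
    state.g_exc = state.g_exc * math.exp(-dt / params.tau_AMPA)
    state.g_inh = state.g_inh * math.exp(-dt / params.tau_GABA)
    state.x = 1.0 - (1.0 - state.x) * math.exp(-dt / params.tau_rec)
    state.step += 1
    return state


def draw_spikes(state: NetworkState, params: NeuronParams) -> np.ndarray:
    """Draw one uniform per neuron and return the ids that fire.

    Refractory neurons never fire (their draw is still consumed so that
    the random stream advances identically for every neuron).
    """
    u = state.rng.random(state.n)
    p = escape_spike_prob(state.v, params)
    spiking = (u < p) & (state.step >= state.refractory_until)
    return np.flatnonzero(spiking)


def fire_and_deliver(state: NetworkState, spiking, params: NeuronParams,
                     ) -> NetworkState:
    """Process spike emissions: resets, refractoriness, STP and queueing.

    For every spiker i the potential is reset to ``v_rest``, the
    class-dependent refractory period starts, and one delayed event per
    target class is queued carrying ``U·x[i]·w[i,j]·g_max`` (release
    computed with the resource *before* depletion). Afterwards
    ``x[i] <- x[i] − U·x[i]``. Finally any events already due are
    delivered.
    """
    spiking = np.asarray(list(spiking), dtype=np.int64)
    if spiking.size and (spiking.min() < 0 or spiking.max() >= state.n):
        raise ValueError("unknown unit id in spiking set")
    exc_targets = state.is_exc
    for i in spiking:
        i = int(i)
        state.v[i] = params.v_rest
        if state.is_exc[i]:
            state.refractory_until[i] = state.step + params.ref_steps_exc
        else:
            state.refractory_until[i] = state.step + params.ref_steps_inh
        release = params.U * state.x[i]
        row = state.w[i]
        if state.is_exc[i]:
            # exc->exc uses the long delay, exc->inh the short one
            inc = release * row * params.g_max_exc
            inc_ee = np.where(exc_targets, inc, 0.0)
            inc_ei = np.where(~exc_targets, inc, 0.0)
            if inc_ee.any():
                state.push_event(state.step + params.delay_steps_EE,
                                 i, True, inc_ee)
            if inc_ei.any():
                state.push_event(state.step + params.delay_steps_other,
                                 i, True, inc_ei)
        else:
            inc = release * row * params.g_max_inh
            if inc.any():
                state.push_event(state.step + params.delay_steps_other,
                                 i, False, inc)
        state.x[i] = state.x[i] - params.U * state.x[i]
    deliver_due_events(state)
    return state


def apply_external_stimulus(state: NetworkState, pattern) -> NetworkState:
    """Add the pattern amplitude to the potential of each targeted unit.

    Targets must be excitatory. Spiking is still decided by the
    stochastic escape rule on the next step; nothing is forced.
    """
    targets = np.asarray(list(pattern.targets), dtype=np.int64)
    if targets.size == 0:
        return state
    if targets.min() < 0 or targets.max() >= state.n:
        raise ValueError("pattern targets unknown unit id")
    if not state.is_exc[targets].all():
        raise ValueError("stimulus patterns may target excitatory units only")
    state.v[targets] += pattern.amplitude
    return state
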