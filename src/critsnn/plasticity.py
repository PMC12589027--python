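"""STDP window functions and event-driven per-synapse weight updates.

Two window shapes are used depending on the *presynaptic* class:

* excitatory synapses get a temporally asymmetric exponential window
  (potentiation for post-after-pre, depression scaled by ``beta_E``
  otherwise);
* inhibitory synapses get a symmetric difference-of-exponentials window
  whose depression share is set by ``beta_I``.

Updates are all-to-all: each spike pairs with *every* strictly earlier
spike on the opposite side of the synapse. This is realised exactly with
exponential trace accumulators, one per window time constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import STDPParams

__all__ = [
    "window_E",
    "window_I",
    "PlasticityTraces",
    "on_spike_update",
    "clip_weight",
]


def window_E(delta_t, params: STDPParams):
    """Excitatory STDP window F_E(t_post − t_pre).

    ``A_E·exp(−t/τ_E)`` for t >= 0, ``−A_E·β_E·exp(t/τ_E)`` for t < 0.
    Accepts scalars or arrays.
    """
    t = np.asarray(delta_t, dtype=np.float64)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite time difference")
    out = np.where(
        t >= 0,
        params.A_E * np.exp(-t / params.tau_E),
        -params.A_E * params.beta_E * np.exp(t / params.tau_E),
    )
    return float(out) if out.ndim == 0 else out


def window_I(delta_t, params: STDPParams):
    """Inhibitory STDP window F_I(t), symmetric in t.

    ``c1·exp(−|t|/τ_I1) − c2·exp(−|t|/τ_I2)`` with
    ``c1 = A_I/(1 − (τ_I1/τ_I2)β_I)`` and ``c2 = c1·(τ_I1/τ_I2)β_I``;
    F_I(0) = A_I for any admissible ``beta_I``.
    """
    t = np.abs(np.asarray(delta_t, dtype=np.float64))
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite time difference")
    out = params.c1 * np.exp(-t / params.tau_I1) \
        - params.c2 * np.exp(-t / params.tau_I2)
    return float(out) if out.ndim == 0 else out


def clip_weight(w: float, lo: float = 0.0, hi: float = 1.0) -> float:
    return min(max(w, lo), hi)


@dataclass
class _SideTrace:
    """Exponential accumulators over one side's spike history.

    ``e``, ``i1`` and ``i2`` hold Σ exp(−(t_last − t_s)/τ) over all spikes
    t_s <= t_last for the three window time constants. ``n_at_last``
    counts spikes at exactly ``t_last`` so that queries at the same time
    can exclude coincident events (pairing is with *strictly earlier*
    spikes only).
    """

    t_last: float = -math.inf
    e: float = 0.0
    i1: float = 0.0
    i2: float = 0.0
    n_at_last: int = 0

    def _decay(self, t: float, params: STDPParams) -> tuple[float, float, float]:
        if not t >= self.t_last:
            raise ValueError("events must be processed in time order")
        if math.isinf(self.t_last):
            return 0.0, 0.0, 0.0
        dt = t - self.t_last
        return (
            self.e * math.exp(-dt / params.tau_E),
            self.i1 * math.exp(-dt / params.tau_I1),
            self.i2 * math.exp(-dt / params.tau_I2),
        )

    def values(self, t: float, params: STDPParams, *,
               include_coincident: bool) -> tuple[float, float, float]:
        """Trace values at time t, optionally excluding spikes at t."""
        e, i1, i2 = self._decay(t, params)
        if not include_coincident and t == self.t_last and self.n_at_last:
            e -= self.n_at_last
            i1 -= self.n_at_last
            i2 -= self.n_at_last
        return e, i1, i2

    def add_spike(self, t: float, params: STDPParams) -> None:
        e, i1, i2 = self._decay(t, params)
        self.n_at_last = self.n_at_last + 1 if t == self.t_last else 1
        self.t_last = t
        self.e, self.i1, self.i2 = e + 1.0, i1 + 1.0, i2 + 1.0


@dataclass
class PlasticityTraces:
    """Pre-side and post-side spike-history traces of one synapse."""

    pre: _SideTrace = field(default_factory=_SideTrace)
    post: _SideTrace = field(default_factory=_SideTrace)


def on_spike_update(w: float, spike: tuple[float, str],
                    traces: PlasticityTraces, params: STDPParams,
                    pre_is_exc: bool) -> float:
    """Process one spike event on a synapse and return the new weight.

    ``spike`` is ``(time_ms, role)`` with role ``"pre"`` or ``"post"``.
    On a presynaptic spike the weight moves by the summed window over
    all strictly earlier postsynaptic spikes, and vice versa (the pair
    sums run over spikes *before* the triggering one, so coincident
    pre/post spikes do not pair). The result is clipped to [0, 1].
    Events must arrive in nondecreasing time order (out-of-order input
    raises).

    The trace realisation is exactly equivalent to the explicit
    double-sum over the full spike history.
    """
    t, role = spike
    if role == "pre":
        other, own = traces.post, traces.pre
        # t_post < t_pre: depression branch of F_E; F_I is symmetric
        e, i1, i2 = other.values(t, params, include_coincident=False)
        if pre_is_exc:
            dw = -params.A_E * params.beta_E * e
        else:
            dw = params.c1 * i1 - params.c2 * i2
    elif role == "post":
        other, own = traces.pre, traces.post
        e, i1, i2 = other.values(t, params, include_coincident=False)
        if pre_is_exc:
            dw = params.A_E * e
        else:
            dw = params.c1 * i1 - params.c2 * i2
    else:
        raise ValueError(f"spike role must be 'pre' or 'post', got {role!r}")
    # validate ordering against both sides before mutating anything
    if t < own.t_last:
        raise ValueError("events must be processed in time order")
    own.add_spike(t, params)
    return clip_weight(w + dw)
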