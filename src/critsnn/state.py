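"""Core data containers: spike trains and full network state."""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np

from .params import NeuronParams

__all__ = ["SpikeTrain", "NetworkState", "PendingEvent"]


@dataclass
class SpikeTrain:
    """An ordered set of (time, unit) spike events.

    ``times`` are in seconds, ``units`` are integer unit ids. ``is_exc``
    optionally records the excitatory/inhibitory class of every unit in
    the population (indexed by unit id, not by event).
    """

    times: np.ndarray
    units: np.ndarray
    n_units: int
    is_exc: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.units = np.asarray(self.units, dtype=np.int64)
        if self.times.shape != self.units.shape:
            raise ValueError("times and units must have equal length")
        if self.times.size and (self.units.min() < 0
                                or self.units.max() >= self.n_units):
            raise ValueError("unit id out of range")

    def __len__(self) -> int:
        return self.times.size

    def sorted(self) -> "SpikeTrain":
        """Return a copy ordered by time (ties broken by unit id)."""
        order = np.lexsort((self.units, self.times))
        return SpikeTrain(self.times[order], self.units[order],
                          self.n_units, self.is_exc)

    def in_window(self, t0: float, t1: float) -> "SpikeTrain":
        """Events with t0 <= time < t1, times shifted to start at t0=0."""
        m = (self.times >= t0) & (self.times < t1)
        return SpikeTrain(self.times[m] - t0, self.units[m],
                          self.n_units, self.is_exc)

    def counts(self) -> np.ndarray:
        """Spike count per unit."""
        return np.bincount(self.units, minlength=self.n_units)

    def rate_hz(self, duration_s: float) -> float:
        """Population-mean firing rate over ``duration_s``."""
        if duration_s <= 0:
            raise ValueError("duration must be > 0")
        return len(self) / (self.n_units * duration_s)

    @staticmethod
    def empty(n_units: int, is_exc: np.ndarray | None = None) -> "SpikeTrain":
        return SpikeTrain(np.empty(0), np.empty(0, dtype=np.int64),
                          n_units, is_exc)

    @staticmethod
    def concatenate(trains: list["SpikeTrain"],
                    offsets_s: list[float] | None = None) -> "SpikeTrain":
        if not trains:
            raise ValueError("nothing to concatenate")
        if offsets_s is None:
            offsets_s = [0.0] * len(trains)
        times = np.concatenate([tr.times + off
                                for tr, off in zip(trains, offsets_s)])
        units = np.concatenate([tr.units for tr in trains])
        return SpikeTrain(times, units, trains[0].n_units, trains[0].is_exc)


@dataclass(order=True)
class PendingEvent:
    """A delayed synaptic delivery.

    ``increment`` is the full vector of postsynaptic conductance
    increments produced by one presynaptic spike (release fraction,
    resource, weight row and maximal conductance folded in at emission
    time). ``exc`` selects the conductance channel of the targets.
    """

    deliver_step: int
    seq: int
    pre: int = field(compare=False)
    exc: bool = field(compare=False)
    increment: np.ndarray = field(compare=False)


class NetworkState:
    """Full mutable simulation state of the network.

    Attributes
    ----------
    step : int
        Discrete clock; the continuous time is ``t = step * dt`` ms.
    v, g_exc, g_inh, x : float arrays (n,)
        Membrane potential, summed synaptic conductances and available
        presynaptic resource of every neuron.
    w : float array (n, n)
        Synaptic weight matrix, ``w[i, j]`` for the synapse pre i -> post j;
        the diagonal is permanently zero (no autapses).
    refractory_until : int array (n,)
        First step index at which the neuron may fire again.
    trace_E, trace_I1, trace_I2 : float arrays (n,)
        Per-neuron exponential spike-history traces used for the
        all-to-all pairing plasticity updates.
    pending : heap of PendingEvent
        Delayed conductance deliveries, ordered by delivery step.
    rng : numpy Generator
        The single noise stream of the simulation.
    """

    def __init__(self, n_exc: int, n_inh: int, params: NeuronParams,
                 rng: np.random.Generator,
                 init_rng: np.random.Generator | None = None):
        n = n_exc + n_inh
        if n_exc <= 0 or n_inh < 0:
            raise ValueError("need at least one excitatory neuron")
        self.params = params
        self.n = n
        self.is_exc = np.zeros(n, dtype=bool)
        self.is_exc[:n_exc] = True
        self.step = 0
        vr = (init_rng if init_rng is not None else rng)
        # initial potentials drawn uniformly between rest and threshold
        self.v = vr.uniform(params.v_rest, params.v_th, size=n)
        self.g_exc = np.zeros(n)
        self.g_inh = np.zeros(n)
        self.x = np.ones(n)
        self.w = np.zeros((n, n))
        self.refractory_until = np.zeros(n, dtype=np.int64)
        self.trace_E = np.zeros(n)
        self.trace_I1 = np.zeros(n)
        self.trace_I2 = np.zeros(n)
        self.pending: list[PendingEvent] = []
        self._seq = itertools.count()
        self.rng = rng

    @property
    def t(self) -> float:
        """Current time in ms."""
        return self.step * self.params.dt

    @property
    def n_exc(self) -> int:
        return int(self.is_exc.sum())

    @property
    def n_inh(self) -> int:
        return self.n - self.n_exc

    def push_event(self, deliver_step: int, pre: int, exc: bool,
                   increment: np.ndarray) -> None:
        heapq.heappush(self.pending,
                       PendingEvent(deliver_step, next(self._seq),
                                    pre, exc, increment))

    def pop_due_events(self) -> list[PendingEvent]:
        due = []
        while self.pending and self.pending[0].deliver_step <= self.step:
            due.append(heapq.heappop(self.pending))
        return due

    def clone(self, rng: np.random.Generator) -> "NetworkState":
        """Deep copy of the dynamical state with a fresh noise stream."""
        new = NetworkState.__new__(NetworkState)
        new.params = self.params
        new.n = self.n
        new.is_exc = self.is_exc.copy()
        new.step = self.step
        for name in ("v", "g_exc", "g_inh", "x", "w", "refractory_until",
                     "trace_E", "trace_I1", "trace_I2"):
            setattr(new, name, getattr(self, name).copy())
        new.pending = [PendingEvent(e.deliver_step, e.seq, e.pre, e.exc,
                                    e.increment.copy())
                       for e in self.pending]
        new._seq = itertools.count(len(new.pending))
        new.rng = rng
        return new

    def state_hash(self) -> int:
        """Hash of the dynamical arrays, for no-mutation assertions."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.int64(self.step).tobytes())
        for name in ("v", "g_exc", "g_inh", "x", "w", "refractory_until"):
            h.update(np.ascontiguousarray(getattr(self, name)).tobytes())
        return int.from_bytes(h.digest()[:8], "little")
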