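"""Excitation-inhibition balance metrics from synaptic-current traces."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CurrentTraces", "EIBalanceResult", "ei_metrics"]


@dataclass
class CurrentTraces:
    """Per-neuron excitatory and inhibitory synaptic-current traces.

    ``E[i, t] = (E_exc − v)·g_exc`` (non-negative in the model's potential
    range) and ``I[i, t] = (E_inh − v)·g_inh`` (non-positive), sampled
    every ``dt_ms``.
    """

    dt_ms: float
    E: np.ndarray  # (n_neurons, n_samples)
    I: np.ndarray

    def __post_init__(self) -> None:
        self.E = np.atleast_2d(np.asarray(self.E, dtype=np.float64))
        self.I = np.atleast_2d(np.asarray(self.I, dtype=np.float64))
        if self.E.shape != self.I.shape:
            raise ValueError("E and I traces must have equal shapes")
        if not (np.isfinite(self.E).all() and np.isfinite(self.I).all()):
            raise ValueError("non-finite current values")

    @property
    def n_neurons(self) -> int:
        return self.E.shape[0]

    @property
    def duration_s(self) -> float:
        return self.E.shape[1] * self.dt_ms / 1000.0


@dataclass
class EIBalanceResult:
    cc: float          # mean zero-lag correlation of E and −I, in [−1, 1]
    mean_E: float      # time-and-neuron mean excitatory input magnitude
    mean_I: float      # same for |inhibitory| input
    ie_ratio: float    # mean_I / mean_E
    n_valid: int       # neurons with nonzero variance in both traces
    flagged: bool = False  # True when cc or the ratio is undefined


def ei_metrics(traces: CurrentTraces, window_s: float = 2.0,
               start_s: float = 0.0) -> EIBalanceResult:
    """EI-balance metrics over a window of the current traces.

    Per neuron, the zero-lag Pearson correlation between E(t) and −I(t)
    is computed; neurons with a constant trace are excluded and ``cc`` is
    the mean over the rest. The inhibitory trace is sign-flipped so that
    tight balance reads as cc ≈ +1. Magnitudes are plain time-and-neuron
    means of E and |I|, and ``ie_ratio`` their quotient.
    """
    i0 = int(round(start_s * 1000.0 / traces.dt_ms))
    i1 = i0 + int(round(window_s * 1000.0 / traces.dt_ms))
    if i0 < 0 or i1 > traces.E.shape[1] or i1 <= i0:
        raise ValueError("window does not fit within the traces")
    E = traces.E[:, i0:i1]
    nI = -traces.I[:, i0:i1]

    Ec = E - E.mean(axis=1, keepdims=True)
    Ic = nI - nI.mean(axis=1, keepdims=True)
    sE = np.sqrt((Ec ** 2).sum(axis=1))
    sI = np.sqrt((Ic ** 2).sum(axis=1))
    valid = (sE > 0) & (sI > 0)
    if valid.any():
        cc_per = (Ec[valid] * Ic[valid]).sum(axis=1) \
            / (sE[valid] * sI[valid])
        cc = float(cc_per.mean())
        flagged = False
    else:
        cc = float("nan")
        flagged = True
    mean_E = float(np.abs(E).mean())
    mean_I = float(np.abs(nI).mean())
    if mean_E > 0:
        ie_ratio = mean_I / mean_E
    else:
        ie_ratio = float("nan")
        flagged = True
    return EIBalanceResult(cc=cc, mean_E=mean_E, mean_I=mean_I,
                           ie_ratio=ie_ratio, n_valid=int(valid.sum()),
                           flagged=flagged)
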