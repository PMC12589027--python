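"""Model parameter containers and validation.

All potentials are in mV, all times in ms, conductances are dimensionless
(normalised by the resting conductance), and rates are in Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "NeuronParams",
    "STDPParams",
    "STDP_PRESETS",
    "preset_stdp",
]

#: Named (beta_E, beta_I) operating points producing the three dynamical
#: regimes used throughout the analyses.
STDP_PRESETS: dict[str, tuple[float, float]] = {
    "crt": (1.0, 1.15),  # critical
    "sub": (1.2, 1.2),   # subcritical
    "sup": (1.0, 1.0),   # supercritical
}


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of the escape-noise LIF neuron with conductance synapses.

    Defaults reproduce the reference parameter set used for all
    experiments (cortical-pyramidal-like values).
    """

    dt: float = 0.1            # integration timestep (ms)
    tau_m: float = 30.0        # membrane time constant (ms)
    v_rest: float = -74.0      # resting potential (mV)
    v_th: float = -54.0        # soft firing threshold (mV)
    E_exc: float = 0.0         # excitatory reversal potential (mV)
    E_inh: float = -80.0       # inhibitory reversal potential (mV)
    g_rest: float = 1.0        # resting (leak) conductance, fixed to 1
    f_rest: float = 0.4        # spontaneous firing rate at rest (Hz)
    b: float = 4.0             # escape-noise sharpness (mV)
    tau_AMPA: float = 2.0      # excitatory conductance decay (ms)
    tau_GABA: float = 4.0      # inhibitory conductance decay (ms)
    T_ref_exc: float = 3.0     # refractory period, excitatory (ms)
    T_ref_inh: float = 2.0     # refractory period, inhibitory (ms)
    U: float = 0.4             # release fraction per presynaptic spike
    tau_rec: float = 150.0     # resource recovery time constant (ms)
    g_max_exc: float = 4.0     # maximal excitatory conductance
    g_max_inh: float = 4.0     # maximal inhibitory conductance
    delay_EE: float = 1.5      # exc->exc synaptic delay (ms)
    delay_other: float = 0.8   # all other synaptic delays (ms)

    def __post_init__(self) -> None:
        for name in ("dt", "tau_m", "tau_AMPA", "tau_GABA", "tau_rec",
                     "T_ref_exc", "T_ref_inh", "b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 < self.U <= 1.0:
            raise ValueError(f"U must lie in (0, 1], got {self.U}")
        if self.v_rest >= self.v_th:
            raise ValueError(
                f"v_rest ({self.v_rest}) must be below v_th ({self.v_th})"
            )
        if self.f_rest < 0:
            raise ValueError(f"f_rest must be >= 0, got {self.f_rest}")

    @property
    def escape_prefactor(self) -> float:
        """Per-step firing probability prefactor Δt/τ.

        Calibrated so a neuron sitting at ``v_rest`` fires at ``f_rest``:
        Δt/τ = f_rest · Δt · exp((v_th − v_rest)/b), with Δt converted
        from ms to s so that f_rest·Δt is a dimensionless probability.
        """
        return self.f_rest * self.dt * 1e-3 * math.exp(
            (self.v_th - self.v_rest) / self.b
        )

    @property
    def delay_steps_EE(self) -> int:
        return int(round(self.delay_EE / self.dt))

    @property
    def delay_steps_other(self) -> int:
        return int(round(self.delay_other / self.dt))

    @property
    def ref_steps_exc(self) -> int:
        return int(round(self.T_ref_exc / self.dt))

    @property
    def ref_steps_inh(self) -> int:
        return int(round(self.T_ref_inh / self.dt))

    def replace(self, **kw) -> "NeuronParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class STDPParams:
    """Spike-timing-dependent plasticity window parameters.

    The excitatory window is temporally asymmetric with
    potentiation/depression balance ``beta_E``; the inhibitory window is
    symmetric with balance ``beta_I`` and requires
    ``tau_I1/tau_I2 < min(1/beta_I, 1)`` so its peak stays positive.
    """

    A_E: float = 0.02
    A_I: float = 0.02
    tau_E: float = 20.0
    tau_I1: float = 10.0
    tau_I2: float = 20.0
    beta_E: float = 1.0
    beta_I: float = 1.15

    def __post_init__(self) -> None:
        if self.A_E <= 0 or self.A_I <= 0:
            raise ValueError("A_E and A_I must be > 0")
        for name in ("tau_E", "tau_I1", "tau_I2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.beta_I <= 0 or self.beta_E < 0:
            raise ValueError("beta_E must be >= 0 and beta_I > 0")
        ratio = self.tau_I1 / self.tau_I2
        if not ratio < min(1.0 / self.beta_I, 1.0):
            raise ValueError(
                "inhibitory window constraint violated: "
                f"tau_I1/tau_I2 = {ratio:.4g} must be < "
                f"min(1/beta_I, 1) = {min(1.0 / self.beta_I, 1.0):.4g}"
            )

    @property
    def kappa(self) -> float:
        """tau_I1/tau_I2, the shape ratio of the inhibitory window."""
        return self.tau_I1 / self.tau_I2

    @property
    def c1(self) -> float:
        """Prefactor of the fast (tau_I1) inhibitory-window exponential."""
        return self.A_I / (1.0 - self.kappa * self.beta_I)

    @property
    def c2(self) -> float:
        """Prefactor of the slow (tau_I2) inhibitory-window exponential."""
        return self.c1 * self.kappa * self.beta_I

    def replace(self, **kw) -> "STDPParams":
        return replace(self, **kw)


def preset_stdp(name: str, **overrides) -> STDPParams:
    """Return the STDP parameters for a named regime preset.

    Presets: ``crt`` (beta_E=1, beta_I=1.15), ``sub`` (1.2, 1.2),
    ``sup`` (1, 1).
    """
    try:
        beta_e, beta_i = STDP_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(STDP_PRESETS)}"
        ) from None
    return STDPParams(beta_E=beta_e, beta_I=beta_i, **overrides)
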