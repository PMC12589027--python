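"""Synthetic data generators with known ground truth.

Every analysis stage in the package can be exercised against these
generators without running the full simulator: branching-process
avalanche trains with a known branching ratio, labeled evoked responses
with controllable class separation, current-trace pairs with a target
correlation, and MEA-like recordings carrying stimulation artifacts.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoding import TrialSet
from .ei_balance import CurrentTraces
from .state import SpikeTrain

__all__ = [
    "BranchingConfig",
    "branching_process_spikes",
    "labeled_response_set",
    "correlated_current_pair",
    "mea_like_recording",
]


@dataclass(frozen=True)
class BranchingConfig:
    """Configuration of the Galton-Watson avalanche-train generator."""

    sigma: float              # branching ratio (mean offspring per spike)
    n_avalanches: int = 10_000
    n_units: int = 100
    # power of two so tick times and their differences are exact floats
    intra_gap_s: float = 2.0 ** -13  # spacing of spikes within an avalanche
    gap_factor: float = 50.0    # inter-avalanche gap / intra gap (ticks)
    size_cap: int | None = None  # per-generation cap; required if sigma >= 1
    total_cap: int | None = None  # hard avalanche-size ceiling (system size)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("branching ratio must be >= 0")
        if self.sigma >= 1 and self.size_cap is None \
                and self.total_cap is None:
            raise ValueError(
                "sigma >= 1 needs a per-generation size cap to terminate")
        if self.gap_factor <= 1:
            raise ValueError("gap_factor must be > 1")
        if self.n_avalanches < 2:
            raise ValueError("need at least 2 avalanches")


def _gw_size(rng: np.random.Generator, sigma: float, cap: int | None,
             total_cap: int | None = None) -> int:
    """Total progeny of one Poisson Galton-Watson cascade.

    ``cap`` bounds a single generation (resource limit), ``total_cap``
    hard-bounds the whole cascade at the system size, piling runaway
    cascades up at that size.
    """
    size = 1
    gen = 1
    while gen > 0:
        gen = int(rng.poisson(sigma * gen))
        if cap is not None and gen > cap:
            gen = cap
        size += gen
        if total_cap is not None and size >= total_cap:
            return total_cap
        if cap is not None and size > 100 * cap:
            break  # runaway supercritical cascade; truncate
    return size


def branching_process_spikes(config: BranchingConfig,
                             ) -> tuple[SpikeTrain, np.ndarray]:
    """Avalanche train from a Poisson Galton-Watson branching process.

    Spikes within one avalanche are packed one tick (``intra_gap_s``)
    apart and avalanches are separated by ``round(gap_factor)`` ticks.
    Times are laid out on an integer tick grid scaled by a power of two,
    so consecutive differences are *exact* floats and segmentation by
    the mean-ISI rule recovers the true sizes exactly. Returns the spike
    train and the ground-truth avalanche sizes.
    """
    rng = np.random.default_rng(config.seed)
    sizes = np.array([_gw_size(rng, config.sigma, config.size_cap,
                               config.total_cap)
                      for _ in range(config.n_avalanches)], dtype=np.int64)
    inter_ticks = int(round(config.gap_factor))
    ticks = np.empty(int(sizes.sum()), dtype=np.int64)
    pos = 0
    t = 0
    for s in sizes:
        ticks[pos:pos + s] = t + np.arange(s)
        pos += s
        t = ticks[pos - 1] + inter_ticks
    times = ticks.astype(np.float64) * config.intra_gap_s
    units = rng.integers(0, config.n_units, size=times.size)
    return SpikeTrain(times, units, config.n_units), sizes


def labeled_response_set(n_classes: int = 4, n_trials: int = 40,
                         n_units: int = 100, separation: float = 3.0,
                         noise_sd: float = 1.0,
                         signal_bins: tuple[int, int] = (0, 5),
                         bin_width_ms: float = 20.0,
                         window_s: float = 0.5, base_rate: float = 1.0,
                         seed: int = 0) -> TrialSet:
    """Labeled evoked responses with controllable class separation.

    Each class has a distinct binary spatial pattern; during the bins in
    ``signal_bins`` (half-open index range), units belonging to the
    pattern emit ``separation`` extra spikes per bin on average. Spike
    counts are Gaussian around the class mean (sd ``noise_sd``), rounded
    and clipped at zero; spikes are placed uniformly within their bin.
    With ``separation = 0`` the trials carry no class information.
    """
    if min(n_classes, n_trials, n_units) <= 0:
        raise ValueError("counts must be > 0")
    rng = np.random.default_rng(seed)
    # one random half-on binary pattern per class
    patterns = rng.random((n_classes, n_units)) < 0.5
    n_bins = int(round(window_s * 1000.0 / bin_width_ms))
    bw_s = bin_width_ms / 1000.0
    labels, trains = [], []
    for c in range(n_classes):
        for _ in range(n_trials):
            t_all, u_all = [], []
            for b in range(n_bins):
                mu = np.full(n_units, base_rate * bw_s)
                if signal_bins[0] <= b < signal_bins[1]:
                    mu = mu + separation * patterns[c]
                counts = np.rint(mu + noise_sd * rng.standard_normal(n_units))
                counts = np.clip(counts, 0, None).astype(np.int64)
                for u in np.flatnonzero(counts):
                    t_all.append(b * bw_s
                                 + rng.random(counts[u]) * bw_s)
                    u_all.append(np.full(counts[u], u, dtype=np.int64))
            if t_all:
                times = np.concatenate(t_all)
                units = np.concatenate(u_all)
            else:
                times = np.empty(0)
                units = np.empty(0, dtype=np.int64)
            labels.append(f"S{c}")
            trains.append(SpikeTrain(times, units, n_units))
    return TrialSet(labels=np.array(labels), trains=trains,
                    n_units=n_units, window_s=window_s)


def correlated_current_pair(rho_target: float, n_samples: int = 20_000,
                            dt_ms: float = 0.1, seed: int = 0,
                            ) -> CurrentTraces:
    """One neuron's (E, I) traces with a chosen population correlation.

    E and −I share a common Gaussian component mixed so that
    corr(E, −I) = ``rho_target``; I is returned negative (inhibitory
    convention) around a positive offset so the traces look like
    conductance-driven currents.
    """
    if not 0.0 <= rho_target <= 1.0:
        raise ValueError("rho_target must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal(n_samples)
    a = np.sqrt(rho_target)
    b = np.sqrt(1.0 - rho_target)
    e = a * shared + b * rng.standard_normal(n_samples)
    i = a * shared + b * rng.standard_normal(n_samples)
    E = 10.0 + e
    I = -(10.0 + i)
    return CurrentTraces(dt_ms=dt_ms, E=E[None, :], I=I[None, :])


def mea_like_recording(trials: TrialSet, *, stim_times_s=(0.0,),
                       artifact_rate: float = 3.0,
                       artifact_window_ms: float = 1.0,
                       saturated_units=(), seed: int = 0,
                       ) -> tuple[TrialSet, TrialSet]:
    """MEA-style corruption of a clean trial set.

    Injects spurious spikes within ``artifact_window_ms`` after each
    stimulus (Poisson count with mean ``artifact_rate`` per trial) and
    flags the given units as saturated. Returns ``(noisy, clean)`` where
    ``clean`` is the ground truth after perfect artifact removal and
    saturated-unit exclusion, so
    ``preprocess_in_vitro(noisy) == clean`` by construction.
    """
    rng = np.random.default_rng(seed)
    sat = np.zeros(trials.n_units, dtype=bool)
    sat[list(saturated_units)] = True
    stim = np.asarray(stim_times_s, dtype=np.float64)
    w = artifact_window_ms / 1000.0
    noisy_trains, clean_trains = [], []
    for tr in trials.trains:
        # ground truth: drop saturated units and anything in the window
        keep = ~sat[tr.units]
        if stim.size and w > 0:
            off = tr.times[:, None] - stim[None, :]
            keep &= ~((off >= 0) & (off < w)).any(axis=1)
        clean_trains.append(SpikeTrain(tr.times[keep], tr.units[keep],
                                       tr.n_units, tr.is_exc))
        t_parts = [tr.times]
        u_parts = [tr.units]
        for st in stim:
            k = int(rng.poisson(artifact_rate))
            if k:
                t_parts.append(st + rng.random(k) * w)
                u_parts.append(rng.integers(0, trials.n_units, size=k))
        noisy_trains.append(
            SpikeTrain(np.concatenate(t_parts), np.concatenate(u_parts),
                       tr.n_units, tr.is_exc).sorted())
    noisy = TrialSet(labels=trials.labels.copy(), trains=noisy_trains,
                     n_units=trials.n_units, window_s=trials.window_s,
                     saturated=sat.copy())
    clean = TrialSet(labels=trials.labels.copy(), trains=clean_trains,
                     n_units=trials.n_units, window_s=trials.window_s,
                     saturated=sat.copy())
    return noisy, clean
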