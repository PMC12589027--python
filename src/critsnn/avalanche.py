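"""Neuronal avalanche statistics and the ΔCr criticality index.

An avalanche is a maximal run of consecutive spikes (in the merged,
sorted population spike-time series) whose internal gaps are all strictly
smaller than the series' mean inter-spike interval. Its size is the
number of spikes it contains. The size distribution is compared with a
log-log linear (power-law) fit; the signed deviation sums give Δp and
the one-sided index ΔCr (<0 subcritical, ≈0 critical, >0 supercritical).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "PowerLawFit",
    "AvalancheAnalysis",
    "detect_avalanches",
    "size_distribution",
    "fit_power_law",
    "delta_cr",
    "analyze",
]

DEFAULT_S_MAX = 100


@dataclass(frozen=True)
class PowerLawFit:
    slope: float
    intercept: float  # log10 p at s = 1
    s_min: int
    s_max: int

    def p_fit(self, s) -> np.ndarray:
        """Power-law probability 10^(intercept + slope·log10 s)."""
        return 10.0 ** (self.intercept
                        + self.slope * np.log10(np.asarray(s, dtype=float)))


@dataclass
class AvalancheAnalysis:
    sizes: np.ndarray
    delta_t_gap: float  # segmentation threshold = mean ISI (seconds)
    p_emp: dict[int, float]
    fit: PowerLawFit
    delta_p: float
    a_upper: float
    a_lower: float
    delta_cr: float

    def to_dict(self) -> dict:
        d = {
            "n_avalanches": int(len(self.sizes)),
            "delta_t_gap_s": float(self.delta_t_gap),
            "p_emp": {int(k): float(v) for k, v in self.p_emp.items()},
            "fit": asdict(self.fit),
            "delta_p": float(self.delta_p),
            "a_upper": float(self.a_upper),
            "a_lower": float(self.a_lower),
            "delta_cr": float(self.delta_cr),
        }
        return d


def detect_avalanches(spike_times) -> tuple[np.ndarray, float]:
    """Segment a merged spike-time series into avalanches.

    The gap threshold Δt is the mean of consecutive differences of the
    sorted series; spikes whose gap to the previous spike is strictly
    below Δt belong to the same avalanche. Returns (sizes, Δt).
    """
    t = np.sort(np.asarray(spike_times, dtype=np.float64))
    if t.size < 2:
        raise ValueError("need at least 2 spikes to define the mean ISI")
    gaps = np.diff(t)
    dt_gap = float(gaps.mean())
    # boundaries where the gap reaches the threshold
    breaks = np.flatnonzero(gaps >= dt_gap)
    sizes = np.diff(np.concatenate(([0], breaks + 1, [t.size])))
    return sizes.astype(np.int64), dt_gap


def size_distribution(sizes) -> dict[int, float]:
    """Empirical probability of each observed avalanche size."""
    sizes = np.asarray(sizes, dtype=np.int64)
    if sizes.size == 0:
        raise ValueError("empty size list")
    vals, counts = np.unique(sizes, return_counts=True)
    total = sizes.size
    return {int(s): float(c) / total for s, c in zip(vals, counts)}


def fit_power_law(p_emp: dict[int, float],
                  s_max: int = DEFAULT_S_MAX) -> PowerLawFit:
    """Least-squares log-log line with residual-minimising s_min.

    Candidate lower cutoffs range over the observed sizes in
    [1, s_max/4]; for each, a line is fit to (log10 s, log10 p_emp(s))
    over observed sizes in [s_min, s_max] and the candidate minimising
    the per-point mean squared residual wins (ties and sub-1e-9 relative
    improvements -> smallest s_min). The cutoff exists to trim a deviant
    head, so every candidate must retain at least half of the observed
    sizes (and never fewer than 3); sizes above s_max never enter the
    fit.
    """
    obs = np.array(sorted(s for s in p_emp if 1 <= s <= s_max))
    if obs.size < 3:
        raise ValueError(
            f"need >= 3 distinct observed sizes in [1, {s_max}], "
            f"got {obs.size}")
    log_s = np.log10(obs.astype(float))
    log_p = np.log10([p_emp[int(s)] for s in obs])
    min_keep = max(3, (obs.size + 1) // 2)
    candidates = [int(s) for s in obs if s <= s_max / 4]
    if not candidates:
        candidates = [int(obs[0])]
    best = None
    for s_min in candidates:
        m = obs >= s_min
        if m.sum() < min_keep:
            continue
        slope, intercept = np.polyfit(log_s[m], log_p[m], 1)
        resid = log_p[m] - (intercept + slope * log_s[m])
        mse = float(np.mean(resid ** 2))
        if best is None or mse < best[0] * (1.0 - 1e-9) - 1e-18:
            best = (mse, PowerLawFit(float(slope), float(intercept),
                                     s_min, int(s_max)))
    if best is None:
        raise ValueError("no candidate s_min leaves enough points to fit")
    return best[1]


def delta_cr(p_emp: dict[int, float], fit: PowerLawFit,
             s_max: int | None = None) -> tuple[float, float, float, float]:
    """Deviation sums between empirical and fitted distributions.

    Summed over *observed* sizes in [s_min, s_max] (sizes with no
    empirical mass are skipped). Returns (Δp, A_upper, A_lower, ΔCr)
    where ΔCr is the one-sided sum of larger magnitude, favouring
    A_upper on ties.
    """
    s_max = fit.s_max if s_max is None else s_max
    s = np.array([k for k in sorted(p_emp) if fit.s_min <= k <= s_max])
    if s.size == 0:
        return 0.0, 0.0, 0.0, 0.0
    diffs = np.array([p_emp[int(k)] for k in s]) - fit.p_fit(s)
    d_p = float(diffs.sum())
    a_up = float(diffs[diffs > 0].sum())
    a_lo = float(diffs[diffs < 0].sum())
    d_cr = a_up if abs(a_up) >= abs(a_lo) else a_lo
    return d_p, a_up, a_lo, d_cr


def analyze(spike_times, s_max: int = DEFAULT_S_MAX) -> AvalancheAnalysis:
    """Full pipeline: segmentation, distribution, fit and indices."""
    sizes, dt_gap = detect_avalanches(spike_times)
    p_emp = size_distribution(sizes)
    fit = fit_power_law(p_emp, s_max=s_max)
    d_p, a_up, a_lo, d_cr = delta_cr(p_emp, fit)
    return AvalancheAnalysis(sizes=sizes, delta_t_gap=dt_gap, p_emp=p_emp,
                             fit=fit, delta_p=d_p, a_upper=a_up,
                             a_lower=a_lo, delta_cr=d_cr)
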