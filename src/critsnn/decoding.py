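"""Stimulus-identity decoding and fading-memory decay time.

Population responses are reduced to per-bin firing-rate vectors and
classified with sparse (L1-penalised multinomial) logistic regression.
Memory persistence is the latency at which leave-one-out decoding first
fails an exact one-sided binomial test against the chance rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneOut, StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .state import SpikeTrain

__all__ = [
    "TrialSet",
    "DecodingResult",
    "preprocess_in_vitro",
    "bin_rate_vectors",
    "decode_accuracy",
    "decay_time",
    "compare_conditions",
    "friedman_per_bin",
]

DEFAULT_C = 1.0  # inverse L1 regularisation strength of the decoder


@dataclass
class TrialSet:
    """Labeled evoked-response trials.

    Every trial is a spike train with times relative to stimulus onset
    (seconds). ``saturated`` flags units excluded from analysis (e.g.
    stimulation-saturated electrodes); flagged units contribute no
    features downstream.
    """

    labels: np.ndarray
    trains: list[SpikeTrain]
    n_units: int
    window_s: float | None = None
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.trains):
            raise ValueError("one label per trial required")
        if self.saturated is None:
            self.saturated = np.zeros(self.n_units, dtype=bool)
        else:
            self.saturated = np.asarray(self.saturated, dtype=bool)
            if self.saturated.shape != (self.n_units,):
                raise ValueError("saturated flags must have length n_units")

    def __len__(self) -> int:
        return len(self.trains)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def active_units(self) -> np.ndarray:
        return np.flatnonzero(~self.saturated)


@dataclass
class DecodingResult:
    """Per-latency-bin decoding statistics and the memory decay time."""

    bin_width_ms: float
    latencies_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    accuracy: np.ndarray = field(default_factory=lambda: np.empty(0))
    loo_correct: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int))
    p_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_trials: int = 0
    n_classes: int = 0
    decay_time_ms: float = 0.0

    def to_dict(self) -> dict:
        return {
            "bin_width_ms": float(self.bin_width_ms),
            "latencies_ms": [float(v) for v in self.latencies_ms],
            "accuracy": [float(v) for v in self.accuracy],
            "loo_correct": [int(v) for v in self.loo_correct],
            "p_values": [float(v) for v in self.p_values],
            "n_trials": int(self.n_trials),
            "n_classes": int(self.n_classes),
            "decay_time_ms": float(self.decay_time_ms),
        }


def preprocess_in_vitro(trials: TrialSet, stim_times_s=(0.0,),
                        artifact_window_ms: float = 1.0) -> TrialSet:
    """Stimulation-artifact and saturated-unit exclusion.

    Removes spikes falling within ``artifact_window_ms`` after any
    stimulus time and drops all spikes of saturated-flagged units (the
    flags are retained so downstream feature extraction skips those
    units entirely).
    """
    stim = np.asarray(stim_times_s, dtype=np.float64)
    w = artifact_window_ms / 1000.0
    sat = trials.saturated
    out_trains = []
    for tr in trials.trains:
        keep = ~sat[tr.units]
        if w > 0 and stim.size:
            off = tr.times[:, None] - stim[None, :]
            in_artifact = ((off >= 0) & (off < w)).any(axis=1)
            keep &= ~in_artifact
        out_trains.append(SpikeTrain(tr.times[keep], tr.units[keep],
                                     tr.n_units, tr.is_exc))
    return TrialSet(labels=trials.labels.copy(), trains=out_trains,
                    n_units=trials.n_units, window_s=trials.window_s,
                    saturated=sat.copy())


def bin_rate_vectors(trials: TrialSet, bin_width_ms: float = 20.0,
                     latency_ms: float = 0.0,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Firing-rate feature matrix for one latency bin.

    ``X[k, u]`` is the spike count of active unit u in trial k within
    the half-open window [latency, latency + bin_width) ms, divided by
    the bin width (Hz). Returns (X, labels).
    """
    if latency_ms < 0:
        raise ValueError("latency must be >= 0")
    if trials.window_s is not None \
            and (latency_ms + bin_width_ms) / 1000.0 > trials.window_s + 1e-9:
        raise ValueError("bin extends beyond the recorded trial window")
    units = trials.active_units
    if units.size == 0:
        raise ValueError("no active units left after exclusion")
    col = np.full(trials.n_units, -1, dtype=np.int64)
    col[units] = np.arange(units.size)
    t0 = latency_ms / 1000.0
    t1 = (latency_ms + bin_width_ms) / 1000.0
    X = np.zeros((len(trials), units.size))
    for k, tr in enumerate(trials.trains):
        m = (tr.times >= t0) & (tr.times < t1)
        c = col[tr.units[m]]
        c = c[c >= 0]
        if c.size:
            np.add.at(X[k], c, 1.0)
    X /= bin_width_ms / 1000.0
    return X, trials.labels.copy()


def _make_decoder(C: float, seed: int | None):
    # pure-L1 (lasso) multinomial logistic regression
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(l1_ratio=1.0, solver="saga", C=C,
                           max_iter=500, tol=1e-3,
                           random_state=seed),
    )


def decode_accuracy(X: np.ndarray, y: np.ndarray, *, n_splits: int = 10,
                    test_fraction: float = 0.1, seed: int = 0,
                    C: float = DEFAULT_C) -> float:
    """Mean held-out accuracy of the sparse logistic decoder.

    Uses ``n_splits`` independent stratified shuffle splits holding out
    ``test_fraction`` of the trials; features are z-scored on each
    training fold.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to decode")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    # hold out test_fraction of trials, but never fewer than one per class
    n_test = max(int(np.ceil(test_fraction * len(y))), classes.size)
    splitter = StratifiedShuffleSplit(n_splits=n_splits,
                                      test_size=n_test,
                                      random_state=seed)
    accs = []
    for train_idx, test_idx in splitter.split(X, y):
        clf = _make_decoder(C, seed)
        clf.fit(X[train_idx], y[train_idx])
        accs.append(float(clf.score(X[test_idx], y[test_idx])))
    return float(np.mean(accs))


def _loo_correct(X: np.ndarray, y: np.ndarray, C: float, seed: int) -> int:
    correct = 0
    for train_idx, test_idx in LeaveOneOut().split(X):
        clf = _make_decoder(C, seed)
        clf.fit(X[train_idx], y[train_idx])
        correct += int(clf.predict(X[test_idx])[0] == y[test_idx][0])
    return correct


def decay_time(trials: TrialSet, bin_width_ms: float = 20.0,
               alpha: float = 0.05, *, max_latency_ms: float | None = None,
               C: float = DEFAULT_C, seed: int = 0,
               stop_at_decay: bool = True) -> DecodingResult:
    """Fading-memory decay time from per-bin leave-one-out decoding.

    Latency bins are scanned from zero. For each bin the leave-one-out
    correct count k (of n trials) is tested one-sided against the chance
    rate 1/n_classes with an exact binomial test; the decay time is the
    start latency of the first bin with p >= alpha. The 10-split
    cross-validated accuracy is reported per scanned bin as well.

    With ``stop_at_decay`` the scan ends at the first non-significant
    bin (the decay time is already determined there); otherwise all bins
    up to ``max_latency_ms`` are evaluated.
    """
    classes, counts = np.unique(trials.labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.max() != counts.min():
        raise ValueError("trial counts must be balanced across classes")
    if max_latency_ms is None:
        if trials.window_s is None:
            raise ValueError("max_latency_ms required when the trial "
                             "window is unknown")
        max_latency_ms = trials.window_s * 1000.0
    n = len(trials)
    p0 = 1.0 / classes.size
    lats, accs, corrects, pvals = [], [], [], []
    decay = None
    lat = 0.0
    while lat + bin_width_ms <= max_latency_ms + 1e-9:
        X, y = bin_rate_vectors(trials, bin_width_ms, lat)
        k = _loo_correct(X, y, C, seed)
        p = stats.binomtest(k, n, p0, alternative="greater").pvalue
        lats.append(lat)
        corrects.append(k)
        pvals.append(p)
        accs.append(decode_accuracy(X, y, seed=seed, C=C))
        if p >= alpha and decay is None:
            decay = lat
            if stop_at_decay:
                break
        lat += bin_width_ms
    if decay is None:
        # still significant at the end of the recorded window
        decay = lat
    return DecodingResult(
        bin_width_ms=bin_width_ms, latencies_ms=np.array(lats),
        accuracy=np.array(accs), loo_correct=np.array(corrects, dtype=int),
        p_values=np.array(pvals), n_trials=n, n_classes=int(classes.size),
        decay_time_ms=float(decay))


def compare_conditions(results_a, results_b, *,
                       alternative: str = "two-sided") -> dict:
    """Paired comparison of two sets of decoding results.

    ``results_a``/``results_b`` are equal-length sequences of
    :class:`DecodingResult`, paired by index (e.g. the same networks
    before and after stimulation). Returns the Wilcoxon signed-rank test
    on the paired decay times plus per-bin paired tests on the
    cross-validated accuracies over the latency bins common to all
    members.
    """
    a = list(results_a)
    b = list(results_b)
    if len(a) != len(b):
        raise ValueError("conditions must have equal numbers of results")
    if len(a) < 2:
        raise ValueError("need at least 2 paired results")
    da = np.array([r.decay_time_ms for r in a])
    db = np.array([r.decay_time_ms for r in b])
    if np.all(da == db):
        wil_stat, wil_p = float("nan"), 1.0
    else:
        res = stats.wilcoxon(da, db, alternative=alternative)
        wil_stat, wil_p = float(res.statistic), float(res.pvalue)

    n_common = min(min(r.latencies_ms.size for r in a),
                   min(r.latencies_ms.size for r in b))
    per_bin = []
    for i in range(n_common):
        xa = np.array([r.accuracy[i] for r in a])
        xb = np.array([r.accuracy[i] for r in b])
        if np.all(xa == xb):
            per_bin.append({"latency_ms": float(a[0].latencies_ms[i]),
                            "statistic": float("nan"), "p_value": 1.0})
            continue
        res = stats.wilcoxon(xa, xb, alternative=alternative)
        per_bin.append({"latency_ms": float(a[0].latencies_ms[i]),
                        "statistic": float(res.statistic),
                        "p_value": float(res.pvalue)})
    return {
        "decay_time": {"statistic": wil_stat, "p_value": wil_p,
                       "alternative": alternative},
        "per_bin": per_bin,
    }


def friedman_per_bin(*conditions) -> list[dict]:
    """Per-bin Friedman chi-square test across three or more conditions.

    Each condition is a sequence of :class:`DecodingResult` paired by
    index across conditions; the test is run on the cross-validated
    accuracies of every latency bin common to all results.
    """
    if len(conditions) < 3:
        raise ValueError("the Friedman test needs at least 3 conditions")
    sizes = {len(c) for c in conditions}
    if len(sizes) != 1:
        raise ValueError("conditions must have equal numbers of results")
    n_common = min(r.latencies_ms.size for c in conditions for r in c)
    out = []
    ref = conditions[0][0]
    for i in range(n_common):
        samples = [np.array([r.accuracy[i] for r in c]) for c in conditions]
        res = stats.friedmanchisquare(*samples)
        out.append({"latency_ms": float(ref.latencies_ms[i]),
                    "statistic": float(res.statistic),
                    "p_value": float(res.pvalue)})
    return out
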