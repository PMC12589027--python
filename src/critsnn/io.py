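"""File formats: spike TSV, config files, HDF5 checkpoints and trials.

Spike trains travel as TSV (columns ``time_s``, ``unit_id``) with an
optional JSON sidecar of unit metadata; simulation state and trial sets
use HDF5; analysis results and manifests are JSON. All randomness in a
run flows from the named seeds recorded in the manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import yaml

from . import __version__ as _version
from .decoding import TrialSet
from .engine import ProtocolConfig
from .params import NeuronParams, STDPParams, STDP_PRESETS, preset_stdp
from .state import NetworkState, SpikeTrain

__all__ = [
    "read_spikes",
    "write_spikes",
    "load_config",
    "RunConfig",
    "RunManifest",
    "save_checkpoint",
    "load_checkpoint",
    "write_trials",
    "read_trials",
]


# ---------------------------------------------------------------- spikes


def write_spikes(train: SpikeTrain, path, metadata: bool = True) -> None:
    """Write a spike train as TSV, plus a JSON sidecar of unit metadata."""
    train = train.sorted()
    with open(path, "w") as fh:
        fh.write("time_s\tunit_id\n")
        for t, u in zip(train.times, train.units):
            fh.write(f"{float(t)!r}\t{int(u)}\n")
    if metadata:
        meta = {
            "version": _version,
            "n_units": int(train.n_units),
            "is_exc": (None if train.is_exc is None
                       else [bool(v) for v in train.is_exc]),
        }
        with open(f"{path}.meta.json", "w") as fh:
            json.dump(meta, fh)


def read_spikes(path, n_units: int | None = None) -> SpikeTrain:
    """Read a TSV spike train; input is sorted on load.

    Malformed rows, negative times and out-of-range unit ids raise with
    the offending line number. Unit metadata is taken from the sidecar
    when present, else ``n_units`` (or max id + 1) is used.
    """
    import os

    times, units = [], []
    with open(path) as fh:
        header = fh.readline()
        if header.split() != ["time_s", "unit_id"]:
            raise ValueError(f"{path}: line 1: expected header "
                             "'time_s\\tunit_id'")
        for ln, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {ln}: expected 2 fields")
            try:
                t = float(parts[0])
                u = int(parts[1])
            except ValueError:
                raise ValueError(
                    f"{path}: line {ln}: non-numeric field") from None
            if not np.isfinite(t) or t < 0:
                raise ValueError(f"{path}: line {ln}: invalid time {t}")
            if u < 0:
                raise ValueError(f"{path}: line {ln}: invalid unit id {u}")
            times.append(t)
            units.append(u)
    is_exc = None
    meta_path = f"{path}.meta.json"
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = json.load(fh)
        n_units = int(meta["n_units"])
        if meta.get("is_exc") is not None:
            is_exc = np.array(meta["is_exc"], dtype=bool)
    if n_units is None:
        n_units = (max(units) + 1) if units else 0
    if units and max(units) >= n_units:
        ln = 2 + int(np.argmax(np.array(units) >= n_units))
        raise ValueError(f"{path}: line {ln}: unit id out of range")
    return SpikeTrain(np.array(times), np.array(units, dtype=np.int64),
                      n_units, is_exc).sorted()


# ---------------------------------------------------------------- config


@dataclass
class RunConfig:
    neuron: NeuronParams
    stdp: STDPParams
    protocol: ProtocolConfig


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a YAML/JSON configuration.

    Missing fields take the model defaults. A ``preset`` key selects one
    of the named (beta_E, beta_I) operating points (``crt``, ``sub``,
    ``sup``); explicit ``stdp`` fields override the preset. Constraint
    violations are reported with the offending field.
    """
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known = {"preset", "neuron", "stdp", "protocol"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")

    def build(cls, section, extra=None):
        kwargs = dict(extra or {})
        kwargs.update(raw.get(section) or {})
        valid = set(cls.__dataclass_fields__)
        bad = set(kwargs) - valid
        if bad:
            raise ValueError(
                f"unknown field(s) in '{section}': {sorted(bad)}")
        try:
            return cls(**kwargs)
        except ValueError as e:
            raise ValueError(f"invalid '{section}' config: {e}") from e

    extra_stdp = {}
    if "preset" in raw:
        name = raw["preset"]
        if name not in STDP_PRESETS:
            raise ValueError(f"unknown preset {name!r}; "
                             f"choose from {sorted(STDP_PRESETS)}")
        be, bi = STDP_PRESETS[name]
        extra_stdp = {"beta_E": be, "beta_I": bi}
    return RunConfig(
        neuron=build(NeuronParams, "neuron"),
        stdp=build(STDPParams, "stdp", extra_stdp),
        protocol=build(ProtocolConfig, "protocol"),
    )


# ------------------------------------------------------------ checkpoint


def save_checkpoint(state: NetworkState, path) -> None:
    """Save the full dynamical state (arrays + pending events + RNG)."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = _version
        f.attrs["step"] = state.step
        f.attrs["rng_state"] = json.dumps(
            state.rng.bit_generator.state)
        f.attrs["params"] = json.dumps(asdict(state.params))
        for name in ("v", "g_exc", "g_inh", "x", "w", "refractory_until",
                     "trace_E", "trace_I1", "trace_I2", "is_exc"):
            f.create_dataset(name, data=getattr(state, name))
        grp = f.create_group("pending")
        grp.create_dataset(
            "deliver_step",
            data=np.array([e.deliver_step for e in state.pending],
                          dtype=np.int64))
        grp.create_dataset(
            "exc", data=np.array([e.exc for e in state.pending], dtype=bool))
        if state.pending:
            grp.create_dataset(
                "increment",
                data=np.stack([e.increment for e in state.pending]))


def load_checkpoint(path) -> NetworkState:
    with h5py.File(path, "r") as f:
        params = NeuronParams(**json.loads(f.attrs["params"]))
        is_exc = f["is_exc"][:]
        n_exc = int(is_exc.sum())
        n_inh = int((~is_exc).sum())
        rng = np.random.default_rng(0)
        rng.bit_generator.state = json.loads(f.attrs["rng_state"])
        # init_rng absorbs the constructor's initial-v draw so the
        # restored noise stream is not advanced
        state = NetworkState(n_exc, n_inh, params, rng,
                             init_rng=np.random.default_rng(0))
        state.step = int(f.attrs["step"])
        for name in ("v", "g_exc", "g_inh", "x", "w", "refractory_until",
                     "trace_E", "trace_I1", "trace_I2"):
            setattr(state, name, f[name][:])
        state.is_exc = is_exc.astype(bool)
        ds = f["pending/deliver_step"][:]
        exc = f["pending/exc"][:]
        inc = f["pending/increment"][:] if len(ds) else None
        state.pending = []
        for k in range(len(ds)):
            state.push_event(int(ds[k]), -1, bool(exc[k]), inc[k].copy())
    return state


# ----------------------------------------------------------------- trials


def write_trials(trials: TrialSet, path) -> None:
    """Store a labeled trial set in HDF5 (offsets per trial + flags)."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = _version
        f.attrs["n_units"] = trials.n_units
        if trials.window_s is not None:
            f.attrs["window_s"] = trials.window_s
        f.create_dataset("labels",
                         data=np.array([str(x) for x in trials.labels],
                                       dtype=h5py.string_dtype()))
        f.create_dataset("saturated", data=trials.saturated)
        times = np.concatenate([tr.times for tr in trials.trains]) \
            if trials.trains else np.empty(0)
        units = np.concatenate([tr.units for tr in trials.trains]) \
            if trials.trains else np.empty(0, dtype=np.int64)
        offsets = np.cumsum([0] + [len(tr) for tr in trials.trains])
        f.create_dataset("times", data=times)
        f.create_dataset("units", data=units)
        f.create_dataset("offsets", data=offsets)


def read_trials(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        n_units = int(f.attrs["n_units"])
        window_s = float(f.attrs["window_s"]) if "window_s" in f.attrs \
            else None
        labels = np.array([s.decode() if isinstance(s, bytes) else str(s)
                           for s in f["labels"][:]])
        saturated = f["saturated"][:].astype(bool)
        times = f["times"][:]
        units = f["units"][:].astype(np.int64)
        offsets = f["offsets"][:]
        trains = [SpikeTrain(times[a:b], units[a:b], n_units)
                  for a, b in zip(offsets[:-1], offsets[1:])]
    return TrialSet(labels=labels, trains=trains, n_units=n_units,
                    window_s=window_s, saturated=saturated)


# --------------------------------------------------------------- manifest


@dataclass
class RunManifest:
    """Provenance record tying outputs to their config and seeds."""

    command: str
    config: dict
    seeds: dict
    outputs: dict = field(default_factory=dict)
    code_version: str = _version
    timestamp: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)

    @staticmethod
    def read(path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return RunManifest(**d)
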