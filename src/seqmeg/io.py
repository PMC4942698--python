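"""HDF5 / YAML / CSV interchange.

The HDF5 container layout for a recording:

* ``/data``            -- time x sensor float array
* ``/fs``              -- sampling rate (scalar attribute dataset)
* ``/marker_samples``  -- int array of marker sample indices
* ``/marker_labels``   -- matching UTF-8 label array
* ``/ground_truth/*``  -- optional planted-event table (onset, direction,
  lag_ms, chain as a padded int array with -1 fill)

Classifier containers hold one group per state: ``/state_k/beta`` (slopes
followed by the intercept) and ``/state_k/lambda``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .decode import StateClassifier
from .synth import GroundTruthLog, SensorTimeSeries, SequenceEvent

_STR = h5py.string_dtype(encoding="utf-8")


def save_timeseries(path, ts: SensorTimeSeries,
                    ground_truth: GroundTruthLog | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ts.data)
        f.create_dataset("fs", data=float(ts.fs))
        f.create_dataset("marker_samples",
                         data=np.array([m[0] for m in ts.markers], dtype=np.int64))
        f.create_dataset("marker_labels",
                         data=np.array([m[1] for m in ts.markers], dtype=object),
                         dtype=_STR)
        if ground_truth is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("onset", data=np.array(
                [e.onset for e in ground_truth.events], dtype=np.int64))
            g.create_dataset("direction", data=np.array(
                [e.direction for e in ground_truth.events], dtype=object),
                dtype=_STR)
            g.create_dataset("lag_ms", data=np.array(
                [e.lag_ms for e in ground_truth.events]))
            max_len = max((len(e.chain) for e in ground_truth.events), default=0)
            chains = np.full((len(ground_truth.events), max(max_len, 1)), -1,
                             dtype=np.int64)
            for i, e in enumerate(ground_truth.events):
                chains[i, :len(e.chain)] = e.chain
            g.create_dataset("chain", data=chains)


def load_timeseries(path) -> tuple[SensorTimeSeries, GroundTruthLog | None]:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f["fs"][()])
        samples = f["marker_samples"][()]
        labels = [s.decode() if isinstance(s, bytes) else str(s)
                  for s in f["marker_labels"][()]]
        markers = list(zip((int(i) for i in samples), labels))
        gt = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            gt = GroundTruthLog()
            dirs = [d.decode() if isinstance(d, bytes) else str(d)
                    for d in g["direction"][()]]
            for onset, direction, lag, chain in zip(
                    g["onset"][()], dirs, g["lag_ms"][()], g["chain"][()]):
                gt.events.append(SequenceEvent(
                    onset=int(onset),
                    chain=tuple(int(s) for s in chain if s >= 0),
                    direction=direction, lag_ms=float(lag)))
    return SensorTimeSeries(data=data, fs=fs, markers=markers), gt


def save_classifiers(path, classifiers: Sequence[StateClassifier]) -> None:
    with h5py.File(path, "w") as f:
        for c in classifiers:
            g = f.create_group(f"state_{c.state}")
            g.create_dataset("beta", data=c.beta)
            g.create_dataset("lambda", data=float(c.lam))


def load_classifiers(path) -> list[StateClassifier]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f, key=lambda s: int(s.split("_")[1])):
            beta = f[name]["beta"][()]
            out.append(StateClassifier(
                state=int(name.split("_")[1]), slopes=beta[:-1],
                intercept=float(beta[-1]), lam=float(f[name]["lambda"][()])))
    return out


def probabilities_to_frame(X_trials: Sequence[np.ndarray],
                           bin_ms: float = 10.0,
                           subject: int | None = None) -> pd.DataFrame:
    """Long-format table: trial, time_ms, state (1-based), probability."""
    rows = []
    for t, X in enumerate(X_trials, start=1):
        X = np.asarray(X)
        n_time, n_states = X.shape
        frame = pd.DataFrame({
            "trial": np.repeat(t, n_time * n_states),
            "time_ms": np.tile(np.arange(n_time) * bin_ms, n_states),
            "state": np.repeat(np.arange(1, n_states + 1), n_time),
            "probability": X.flatten(order="F"),
        })
        rows.append(frame)
    out = pd.concat(rows, ignore_index=True)
    if subject is not None:
        out.insert(0, "subject", subject)
    return out


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    return cfg or {}


def dump_config(path, cfg: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)
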