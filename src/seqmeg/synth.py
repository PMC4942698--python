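"""Synthetic sensor-space data with planted state reactivation sequences.

Generates (a) localizer epochs -- evoked responses to direct stimulus
presentations, peaking 200 ms post-onset -- for classifier training, and
(b) planning-period recordings in which brief sequential reactivations of the
state patterns are planted at a configurable state-to-state lag, forward or
reverse along the task graph, on top of temporally autocorrelated (AR(1))
sensor noise. The autocorrelation matters: it is the property that makes
sample-order shuffles anticonservative as a sequenceness null.

Every generator is deterministic under a fixed ``numpy.random.Generator``.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .task import TaskGraph


@dataclasses.dataclass
class SensorTimeSeries:
    """A time x sensor array at fixed sampling rate with event markers.

    ``markers`` is a list of ``(sample_index, label)`` pairs; labels are
    strings (localizer markers use the decimal state id).
    """

    data: np.ndarray
    fs: float
    markers: list[tuple[int, str]] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (time x sensor)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        for idx, _ in self.markers:
            if not (0 <= idx < self.data.shape[0]):
                raise ValueError(f"marker sample {idx} out of range")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass(frozen=True)
class SequenceEvent:
    """One planted reactivation event (ground truth)."""

    onset: int                  # sample index of the first activation
    chain: tuple[int, ...]      # states in *injection* order, 1-based
    direction: str              # "forward" or "reverse"
    lag_ms: float


@dataclasses.dataclass
class GroundTruthLog:
    """Oracle record of all planted events in a planning recording."""

    events: list[SequenceEvent] = dataclasses.field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"onset": e.onset, "direction": e.direction, "lag_ms": e.lag_ms,
             "length": len(e.chain),
             "chain": "-".join(str(s) for s in e.chain)}
            for e in self.events])

    def __len__(self) -> int:
        return len(self.events)


@dataclasses.dataclass
class SyntheticConfig:
    """Knobs of the synthetic generator.

    All durations must be integer multiples of the sample period
    (``1000 / fs`` ms). ``snr`` is the peak activation amplitude expressed in
    units of the stationary noise standard deviation.
    """

    n_sensors: int = 134
    n_states: int = 6
    fs: float = 100.0
    evoked_peak_latency_ms: float = 200.0
    evoked_kernel_width_ms: float = 200.0
    event_rate: float = 1.0         # planted events per second of planning
    lag_ms: float = 40.0            # state-to-state lag within an event
    direction_mix: float = 1.0      # fraction of events injected in reverse
    length_dist: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: {2: 1 / 3, 3: 1 / 3, 4: 1 / 3})
    activation_width_ms: float = 30.0
    snr: float = 6.0
    ar_coeff: float = 0.8
    noise_scale: float = 1.0        # innovation SD of the AR(1) noise

    def __post_init__(self):
        bin_ms = 1000.0 / self.fs
        for name in ("evoked_peak_latency_ms", "lag_ms", "activation_width_ms"):
            v = getattr(self, name)
            if abs(v / bin_ms - round(v / bin_ms)) > 1e-9:
                raise ValueError(f"{name}={v} not a multiple of {bin_ms} ms")
        if not (0 <= self.ar_coeff < 1):
            raise ValueError("ar_coeff must be in [0, 1)")
        if not (0 <= self.direction_mix <= 1):
            raise ValueError("direction_mix must be in [0, 1]")
        total = sum(self.length_dist.values())
        if total <= 0:
            raise ValueError("length_dist must have positive mass")
        self.length_dist = {int(k): v / total for k, v in self.length_dist.items()}

    @property
    def bin_ms(self) -> float:
        return 1000.0 / self.fs

    @property
    def noise_sd(self) -> float:
        """Stationary standard deviation of the AR(1) noise."""
        return self.noise_scale / np.sqrt(1.0 - self.ar_coeff ** 2)


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def make_state_patterns(n_states: int, n_sensors: int,
                        rng: np.random.Generator,
                        max_abs_corr: float = 0.3,
                        max_tries: int = 1000) -> np.ndarray:
    """Random unit-norm spatial patterns, one row per state.

    Rows are resampled until every pairwise |Pearson r| between patterns is
    below ``max_abs_corr`` (rarely needed for >> n_states sensors).
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    for _ in range(max_tries):
        pat = rng.standard_normal((n_states, n_sensors))
        pat /= np.linalg.norm(pat, axis=1, keepdims=True)
        r = np.corrcoef(pat)
        off = np.abs(r[~np.eye(n_states, dtype=bool)])
        if off.max() < max_abs_corr:
            return pat
    raise RuntimeError("could not sample sufficiently decorrelated patterns")


def ar1_noise(n_samples: int, n_sensors: int, ar_coeff: float, scale: float,
              rng: np.random.Generator) -> np.ndarray:
    """Per-sensor AR(1) noise with stationary initialization.

    ``x[t] = ar_coeff * x[t-1] + e[t]``, ``e ~ N(0, scale^2)``; the process is
    started from its stationary distribution so the whole record has variance
    ``scale^2 / (1 - ar_coeff^2)``.
    """
    if not (0 <= ar_coeff < 1):
        raise ValueError("ar_coeff must be in [0, 1)")
    e = rng.normal(0.0, scale, size=(n_samples, n_sensors))
    x0 = rng.normal(0.0, scale / np.sqrt(1 - ar_coeff ** 2), size=n_sensors)
    out, _ = lfilter([1.0], [1.0, -ar_coeff], e, axis=0,
                     zi=(ar_coeff * x0)[None, :])
    return out


def _raised_cosine(width_ms: float, fs: float) -> np.ndarray:
    """Raised-cosine bump sampled over ``width_ms`` with unit peak."""
    n = max(int(round(width_ms * fs / 1000.0)), 1)
    # interior of a Hann window of length n+2: endpoints of the bump are
    # nonzero samples, peak is 1 for odd n
    return np.hanning(n + 2)[1:-1]


# ---------------------------------------------------------------------------
# Localizer
# ---------------------------------------------------------------------------

def simulate_localizer(config: SyntheticConfig, patterns: np.ndarray,
                       n_trials_per_state: int, rng: np.random.Generator,
                       epoch_ms: float = 600.0, pre_ms: float = 100.0
                       ) -> tuple[SensorTimeSeries, np.ndarray]:
    """Simulate a localizer run: one evoked epoch per stimulus presentation.

    Each trial contributes a contiguous segment of ``pre_ms + epoch_ms``;
    the evoked response is ``pattern x raised-cosine kernel`` centred at
    ``evoked_peak_latency_ms`` after onset, scaled to ``snr`` noise SDs.
    Trial order is randomized. Markers mark stimulus onsets and carry the
    state id as label; the returned ``labels`` array (1-based states) is in
    marker order.
    """
    n_states, fs = config.n_states, config.fs
    seg = int(round((pre_ms + epoch_ms) * fs / 1000.0))
    pre = int(round(pre_ms * fs / 1000.0))
    labels = np.repeat(np.arange(1, n_states + 1), n_trials_per_state)
    rng.shuffle(labels)
    n = seg * len(labels)
    data = ar1_noise(n, config.n_sensors, config.ar_coeff, config.noise_scale, rng)

    kernel = _raised_cosine(config.evoked_kernel_width_ms, fs)
    half = len(kernel) // 2
    peak_off = int(round(config.evoked_peak_latency_ms * fs / 1000.0))
    amp = config.snr * config.noise_sd
    markers: list[tuple[int, str]] = []
    for i, state in enumerate(labels):
        onset = i * seg + pre
        lo = onset + peak_off - half
        for j, k in enumerate(kernel):
            t = lo + j
            if 0 <= t < n:
                data[t] += amp * k * patterns[state - 1]
        markers.append((onset, str(int(state))))
    return SensorTimeSeries(data=data, fs=fs, markers=markers), labels


def extract_epochs(ts: SensorTimeSeries, window_ms: tuple[float, float] = (0.0, 500.0)
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slice marker-aligned epochs out of a continuous recording.

    Returns ``(epochs, labels, times_ms)`` where ``epochs`` is
    (n_trials, n_times, n_sensors) and time 0 is marker onset. Markers whose
    window falls outside the recording are dropped.
    """
    lo = int(round(window_ms[0] * ts.fs / 1000.0))
    hi = int(round(window_ms[1] * ts.fs / 1000.0))
    eps, labs = [], []
    for idx, label in ts.markers:
        if idx + lo >= 0 and idx + hi <= ts.n_samples:
            eps.append(ts.data[idx + lo:idx + hi])
            labs.append(int(label))
    times_ms = np.arange(lo, hi) * 1000.0 / ts.fs
    return np.asarray(eps), np.asarray(labs), times_ms


# ---------------------------------------------------------------------------
# Planning period
# ---------------------------------------------------------------------------

def _random_path(graph: TaskGraph, length: int, rng: np.random.Generator
                 ) -> list[int]:
    state = int(rng.integers(1, graph.n_states + 1))
    path = [state]
    for _ in range(length - 1):
        action = "up" if rng.integers(2) == 0 else "down"
        state = graph.successor(state, action)
        path.append(state)
    return path


def simulate_planning(config: SyntheticConfig, patterns: np.ndarray,
                      graph: TaskGraph, duration_s: float,
                      rng: np.random.Generator
                      ) -> tuple[SensorTimeSeries, GroundTruthLog]:
    """Simulate a planning-period recording with planted sequence events.

    Events are Poisson-placed at ``event_rate``. Each event draws a chain
    length from ``length_dist`` and a random directed path along graph edges;
    with probability ``direction_mix`` the path's patterns are injected in
    reversed order (a reverse event). Successive activations within an event
    are offset by ``lag_ms``; each activation is
    ``pattern x raised-cosine(activation_width_ms)`` at ``snr`` noise SDs.
    Events may overlap. The ground-truth log records chains in injection
    order.
    """
    if duration_s < 2:
        raise ValueError("duration must be >= 2 s")
    fs = config.fs
    n = int(round(duration_s * fs))
    data = ar1_noise(n, config.n_sensors, config.ar_coeff, config.noise_scale, rng)

    lag = int(round(config.lag_ms * fs / 1000.0))
    kernel = _raised_cosine(config.activation_width_ms, fs)
    amp = config.snr * config.noise_sd
    lengths = sorted(config.length_dist)
    probs = np.array([config.length_dist[k] for k in lengths])
    max_len = max(lengths)
    max_span = (max_len - 1) * lag + len(kernel)
    if max_span >= n:
        raise ValueError("recording too short for the longest event")

    n_events = rng.poisson(config.event_rate * duration_s)
    onsets = np.sort(rng.integers(0, n - max_span, size=n_events))
    log = GroundTruthLog()
    for onset in onsets:
        L = int(lengths[int(rng.choice(len(lengths), p=probs))])
        path = _random_path(graph, L, rng)
        reverse = rng.random() < config.direction_mix
        chain = path[::-1] if reverse else path
        for m, state in enumerate(chain):
            t0 = int(onset) + m * lag
            data[t0:t0 + len(kernel)] += (
                amp * kernel[:, None] * patterns[state - 1][None, :])
        log.events.append(SequenceEvent(
            onset=int(onset), chain=tuple(chain),
            direction="reverse" if reverse else "forward",
            lag_ms=config.lag_ms))
    markers = [(e.onset, "event") for e in log.events]
    return SensorTimeSeries(data=data, fs=fs, markers=markers), log
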