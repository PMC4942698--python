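"""Minimal preprocessing: anti-aliased decimation and slow-drift removal.

The analysis pipeline operates on 10 ms bins (100 Hz). Recordings acquired at
a higher rate are decimated after low-pass filtering; all data are then
high-pass filtered at 0.5 Hz with a first-order IIR filter.

Filters are applied zero-phase (forward-backward) by default. The lagged
sequenceness statistic is sensitive to phase shifts, so the application mode
is explicit in :class:`FilterSpec` and a causal mode is available.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .synth import SensorTimeSeries


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """High-pass filter specification (first-order IIR by default)."""

    cutoff_hz: float = 0.5
    order: int = 1
    zero_phase: bool = True


def downsample(ts: SensorTimeSeries, target_fs: float) -> SensorTimeSeries:
    """Anti-alias low-pass then decimate to ``target_fs``.

    The decimation factor must be an integer. The anti-alias filter is an
    8th-order Butterworth low-pass at 0.75 x the new Nyquist frequency,
    applied forward-backward; output length is ``ceil(n / q)``. Markers are
    re-indexed to the nearest retained sample.
    """
    q = ts.fs / target_fs
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"non-integer decimation factor {q}")
    q = int(round(q))
    if q == 1:
        return SensorTimeSeries(ts.data.copy(), ts.fs, list(ts.markers))
    sos = signal.butter(8, 0.75 * (target_fs / 2), btype="low",
                        fs=ts.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=0)
    data = filtered[::q]
    markers = [(min(int(round(idx / q)), data.shape[0] - 1), lab)
               for idx, lab in ts.markers]
    return SensorTimeSeries(data=np.ascontiguousarray(data),
                            fs=target_fs, markers=markers)


def highpass(ts: SensorTimeSeries, spec: FilterSpec = FilterSpec()
             ) -> SensorTimeSeries:
    """High-pass filter every sensor, removing DC and slow drift."""
    if spec.cutoff_hz >= ts.fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="high",
                        fs=ts.fs, output="sos")
    if spec.zero_phase:
        data = signal.sosfiltfilt(sos, ts.data, axis=0)
    else:
        data = signal.sosfilt(sos, ts.data, axis=0)
    return SensorTimeSeries(data=np.ascontiguousarray(data), fs=ts.fs,
                            markers=list(ts.markers))
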