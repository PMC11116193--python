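"""Tri-axial acceleration processing: static/dynamic decomposition and VeDBA.

The accelerometer records three body-frame axes (surge: antero-posterior,
sway: lateral, heave: dorso-ventral) in units of g.  The low-frequency
component of each axis — gravity plus slow posture change — is estimated by
a 1 s centered running mean ("static" acceleration); the residual after
subtracting it is the movement-driven "dynamic" acceleration.  VeDBA, the
vectorial dynamic body acceleration, is the per-sample Euclidean norm of
the three dynamic axes and serves as a proxy for mechanical energy
expenditure.  The VeDBA series is finally decimated to 1 Hz to share the
time base of the processed heart-rate data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session import SessionMeta

G_TO_MG = 1000.0


@dataclass
class AccelTrace:
    """Synchronized tri-axial acceleration at a uniform sampling rate.

    Axes are in g; the logger range is +/-8 g.  ``start_time`` anchors the
    trace on the shared session clock (seconds).
    """

    surge: np.ndarray
    sway: np.ndarray
    heave: np.ndarray
    sampling_rate: float = 1600.0
    start_time: float = 0.0
    meta: SessionMeta = field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        self.surge = np.asarray(self.surge, dtype=float)
        self.sway = np.asarray(self.sway, dtype=float)
        self.heave = np.asarray(self.heave, dtype=float)
        if not (len(self.surge) == len(self.sway) == len(self.heave)):
            raise ValueError("axes must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        for ax in (self.surge, self.sway, self.heave):
            if len(ax) and np.nanmax(np.abs(ax)) > 8.0 + 1e-9:
                raise ValueError("acceleration outside the +/-8 g logger range")

    def __len__(self) -> int:
        return len(self.heave)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return len(self) / self.sampling_rate


@dataclass
class VeDBASeries:
    """VeDBA decimated to a uniform 1 Hz grid, in milli-g."""

    times: np.ndarray           # exact integer seconds on the session clock
    vedba: np.ndarray           # mg, >= 0
    meta: SessionMeta = field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vedba = np.asarray(self.vedba, dtype=float)
        if len(self.times) != len(self.vedba):
            raise ValueError("times and vedba must align")
        if len(self.vedba) and self.vedba.min() < 0:
            raise ValueError("VeDBA is non-negative by construction")

    def __len__(self) -> int:
        return len(self.vedba)


def running_mean(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered running mean with shrinking (truncated) windows at the edges.

    Output has the same length as the input; near the edges the window is
    clipped to the available samples rather than padded, so no values are
    invented.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    w = int(window_samples)
    if w <= 0:
        raise ValueError("window must be at least one sample")
    if w > n:
        raise ValueError("window longer than the trace")
    half = w // 2
    # prefix sums give O(n) truncated-window means
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + (w - 1 - half), n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def static_acceleration(trace: AccelTrace, window: float = 1.0):
    """Per-axis running-mean estimate of the static (gravitational) component.

    Parameters
    ----------
    trace : AccelTrace
    window : float
        Smoothing window in seconds (default 1 s).

    Returns
    -------
    (surge, sway, heave) : tuple of ndarray, in g.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    w = int(round(window * trace.sampling_rate))
    if w > len(trace):
        raise ValueError("window longer than the trace")
    w = max(w, 1)
    return (running_mean(trace.surge, w),
            running_mean(trace.sway, w),
            running_mean(trace.heave, w))


def dynamic_acceleration(trace: AccelTrace, static) -> tuple:
    """Dynamic component: raw minus static, per axis (g)."""
    out = []
    for raw, st in zip((trace.surge, trace.sway, trace.heave), static):
        st = np.asarray(st, dtype=float)
        if st.shape != raw.shape:
            raise ValueError("static and raw axes must share shape")
        out.append(raw - st)
    return tuple(out)


def vedba(dynamic) -> np.ndarray:
    """Vectorial dynamic body acceleration, per sample, in mg.

    sqrt(dx^2 + dy^2 + dz^2) of the three dynamic axes.  Inputs may be in g
    (typical) — the result is scaled to milli-g.
    """
    dx, dy, dz = (np.asarray(a, dtype=float) for a in dynamic)
    if not (dx.shape == dy.shape == dz.shape):
        raise ValueError("dynamic axes must align")
    return np.sqrt(dx * dx + dy * dy + dz * dz) * G_TO_MG


def subsample_to_1hz(values: np.ndarray, times: np.ndarray,
                     meta: SessionMeta | None = None) -> VeDBASeries:
    """Decimate a series to 1 Hz by keeping the sample nearest each integer second.

    This is point sub-sampling, not block averaging: each retained value is
    an actual measured sample.  Output timestamps are the exact integer
    seconds covered by the input.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(values) == 0:
        raise ValueError("empty input")
    t0, t1 = times[0], times[-1]
    grid = np.arange(np.ceil(t0 - 1e-9), np.floor(t1 + 1e-9) + 0.5)
    if len(grid) == 0:
        raise ValueError("input spans no integer second")
    # nearest-sample lookup on the (uniform or not) time vector
    pos = np.searchsorted(times, grid)
    pos = np.clip(pos, 1, len(times) - 1)
    left, right = times[pos - 1], times[pos]
    take = np.where(np.abs(grid - left) <= np.abs(right - grid), pos - 1, pos)
    return VeDBASeries(times=grid, vedba=values[take],
                       meta=meta or SessionMeta())


def vedba_1hz(trace: AccelTrace, window: float = 1.0) -> VeDBASeries:
    """Full chain: static estimate -> dynamic -> VeDBA -> 1 Hz decimation."""
    dyn = dynamic_acceleration(trace, static_acceleration(trace, window))
    v = vedba(dyn)
    return subsample_to_1hz(v, trace.times, meta=trace.meta)


def dynamic_heave(trace: AccelTrace, window: float = 1.0) -> np.ndarray:
    """Dynamic heave axis alone (g); the wingbeat-carrying signal."""
    st = running_mean(trace.heave, max(int(round(window * trace.sampling_rate)), 1))
    return trace.heave - st
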