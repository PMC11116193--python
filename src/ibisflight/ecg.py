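"""ECG to heart rate: QRS detection, density filtering, and 5 Hz resampling.

The raw input is a single-lead ECG sampled at 1600 Hz with a +/-6 mV range.
Processing follows four stages:

1. :func:`detect_qrs` — an energy-based R-peak detector (band-pass,
   differentiate, square, moving-window integrate, adaptive threshold).
   When a synchronized dynamic-heave series is supplied, the threshold is
   raised in proportion to local wingbeat intensity, because flapping
   injects motion artifact into the electrodes.
2. :func:`density_filter` — each (time, heart-rate) point is ranked by how
   many other points fall inside a small time-by-rate neighborhood, and
   only the densest fraction is retained.  Physiological beats form a
   dense band; artifact-driven detections are isolated and drop out.
3. :func:`remove_outliers` — a deterministic physiological window
   (60–800 bpm by default) replaces visual outlier deletion.
4. :func:`resample_hr` — instantaneous rate is placed on a uniform 5 Hz
   grid by zero-order hold, with gaps longer than ``max_gap`` left missing
   rather than interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .session import SessionMeta

HR_MIN_DEFAULT = 60.0
HR_MAX_DEFAULT = 800.0


@dataclass
class ECGTrace:
    """Uniformly sampled single-lead ECG voltage series (mV)."""

    samples: np.ndarray
    sampling_rate: float = 1600.0
    start_time: float = 0.0
    meta: SessionMeta = field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.samples) and np.nanmax(np.abs(self.samples)) > 6.0 + 1e-9:
            raise ValueError("ECG outside the +/-6 mV logger range")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return len(self) / self.sampling_rate


@dataclass
class BeatSeries:
    """Detected beats as (time, instantaneous heart rate) points.

    ``times`` are the interval-end R-times; ``hr`` is 60 / RR for the
    interval ending at that time.  ``r_times`` keeps the full strictly
    increasing R-time list when available.  ``diagnostic`` carries a note
    when detection degraded (e.g. flat-line input).
    """

    times: np.ndarray
    hr: np.ndarray
    r_times: np.ndarray | None = None
    diagnostic: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if len(self.times) != len(self.hr):
            raise ValueError("times and hr must align")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    @classmethod
    def from_r_times(cls, r_times: np.ndarray, diagnostic: str = "") -> "BeatSeries":
        r = np.asarray(r_times, dtype=float)
        if len(r) < 2:
            return cls(times=np.array([]), hr=np.array([]), r_times=r,
                       diagnostic=diagnostic or ("fewer than two beats" if len(r) else ""))
        rr = np.diff(r)
        return cls(times=r[1:], hr=60.0 / rr, r_times=r, diagnostic=diagnostic)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def is_empty(self) -> bool:
        return len(self) == 0


@dataclass
class HeartRateSeries:
    """Heart rate on a uniform 5 Hz grid; NaN where the record has a gap."""

    times: np.ndarray
    hr: np.ndarray
    quality: np.ndarray          # "ok" | "gap"
    meta: SessionMeta = field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        self.quality = np.asarray(self.quality)
        if not (len(self.times) == len(self.hr) == len(self.quality)):
            raise ValueError("grid arrays must align")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# QRS detection
# ---------------------------------------------------------------------------

def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    w = max(int(w), 1)
    kernel = np.ones(w) / w
    return signal.convolve(x, kernel, mode="same")


def detect_qrs(ecg: ECGTrace,
               heave_dynamic: np.ndarray | None = None,
               hr_max: float = HR_MAX_DEFAULT,
               band: tuple = (10.0, 45.0),
               integration_window: float = 0.04,
               threshold_frac: float = 0.3,
               activity_gain: float = 0.4,
               noise_window: float = 2.0,
               min_kurtosis: float = 1.0) -> BeatSeries:
    """Detect R-peaks in an ECG trace.

    The detector band-passes the trace (zero-phase Butterworth), squares
    the derivative, integrates over a short moving window, and finds peaks
    above an adaptive threshold.  Per rolling ``noise_window`` the
    threshold sits ``threshold_frac`` of the way from the median energy
    (the floor between beats) up to the 99.5th percentile (the beat
    peaks), and is additionally raised by ``activity_gain`` times the
    local mean |dynamic heave| (g) when ``heave_dynamic`` is supplied — so
    the detector demands stronger evidence during vigorous flapping.
    Candidate peaks are refined to the extremum of the band-passed trace
    so R-times are sample-accurate, and a refractory period of
    60/``hr_max`` s is enforced.

    A flat-line trace, or one whose band-passed excess kurtosis falls
    below ``min_kurtosis`` (pure noise is ~0; any train of QRS spikes is
    well above 1), yields an empty :class:`BeatSeries` with a diagnostic,
    not an exception.
    """
    fs = ecg.sampling_rate
    x = ecg.samples
    if ecg.duration < 2.0:
        raise ValueError("trace shorter than 2 s")
    if fs < 200.0:
        raise ValueError("sampling rate below 200 Hz")

    span = np.nanmax(x) - np.nanmin(x) if len(x) else 0.0
    if span < 1e-6:
        return BeatSeries.from_r_times(np.array([]), diagnostic="flat-line input")

    nyq = fs / 2.0
    lo, hi = band[0] / nyq, min(band[1] / nyq, 0.99)
    b, a = signal.butter(2, [lo, hi], btype="band")
    filt = signal.filtfilt(b, a, x)

    if stats.kurtosis(filt) < min_kurtosis:
        return BeatSeries.from_r_times(
            np.array([]), diagnostic="no QRS-like activity (noise-like trace)")

    deriv = np.gradient(filt) * fs
    energy = _moving_average(deriv ** 2, int(round(integration_window * fs)))

    # rolling energy quantiles on a coarse grid, interpolated back
    wlen = max(int(round(noise_window * fs)), 1)
    starts = np.arange(0, len(x), wlen)
    floor = np.empty(len(starts))
    ceil = np.empty(len(starts))
    for i, s in enumerate(starts):
        chunk = energy[s:s + wlen]
        floor[i] = np.percentile(chunk, 50)
        ceil[i] = np.percentile(chunk, 99.5)
    centers = starts + wlen / 2.0
    floor_i = np.interp(np.arange(len(x)), centers, floor)
    ceil_i = np.interp(np.arange(len(x)), centers, ceil)
    threshold = floor_i + threshold_frac * (ceil_i - floor_i)

    if heave_dynamic is not None:
        hv = np.abs(np.asarray(heave_dynamic, dtype=float))
        if len(hv) != len(x):
            raise ValueError("heave series must align with the ECG")
        activity = _moving_average(hv, wlen)
        # scale the activity floor to the signal's own energy units
        scale = np.percentile(energy, 98)
        threshold = np.maximum(threshold, activity_gain * activity * scale)

    # height filter only: a beat's energy can carry two slope lobes, and
    # distance-pruning on the raw maxima would let a tall secondary lobe
    # suppress the next beat.  Refinement collapses lobes onto the R sample
    # and the refractory is enforced afterwards.
    refractory = int(round(60.0 / hr_max * fs))
    peaks, _ = signal.find_peaks(energy, height=threshold)
    if len(peaks) == 0:
        return BeatSeries.from_r_times(np.array([]),
                                       diagnostic="no peaks above threshold")

    # refine each candidate to the |band-passed| extremum nearby; the
    # search half-width stays under half the refractory so neighbouring
    # beats can never collapse onto one extremum
    half = min(int(round(integration_window * fs)), max(refractory // 2, 1))
    refined = np.empty(len(peaks), dtype=int)
    absf = np.abs(filt)
    for i, p in enumerate(peaks):
        s = max(p - half, 0)
        e = min(p + half + 1, len(x))
        refined[i] = s + int(np.argmax(absf[s:e]))
    refined = np.unique(refined)
    # re-enforce refractory after refinement
    keep = [int(refined[0])]
    for p in refined[1:]:
        if p - keep[-1] >= refractory:
            keep.append(int(p))
    r_times = ecg.start_time + np.asarray(keep) / fs
    return BeatSeries.from_r_times(r_times)


# ---------------------------------------------------------------------------
# density filter / outliers / resampling
# ---------------------------------------------------------------------------

def neighbor_counts(times: np.ndarray, hr: np.ndarray,
                    time_window: float, hr_window: float) -> np.ndarray:
    """Number of OTHER points within +/-time_window and +/-hr_window of each point."""
    times = np.asarray(times, dtype=float)
    hr = np.asarray(hr, dtype=float)
    order = np.argsort(times, kind="stable")
    ts, hs = times[order], hr[order]
    counts = np.empty(len(ts), dtype=int)
    lo = np.searchsorted(ts, ts - time_window, side="left")
    hi = np.searchsorted(ts, ts + time_window, side="right")
    for i in range(len(ts)):
        window = hs[lo[i]:hi[i]]
        counts[i] = int(np.sum(np.abs(window - hs[i]) <= hr_window)) - 1
    out = np.empty(len(ts), dtype=int)
    out[order] = counts
    return out


def density_filter(beats: BeatSeries,
                   time_window: float = 2.0,
                   hr_window: float = 20.0,
                   keep_fraction: float = 0.95) -> BeatSeries:
    """Keep the densest ``keep_fraction`` of beats by neighbor-count rank.

    Each (time, hr) point's neighbor count is the number of other points
    within ``+/-time_window`` seconds and ``+/-hr_window`` bpm.  Points are
    ranked by count (descending) and the top ``ceil(keep_fraction * n)``
    retained; ties at the cut-off count are all kept, and the original
    temporal order is preserved.
    """
    if beats.is_empty:
        raise ValueError("density_filter requires a non-empty BeatSeries")
    if time_window <= 0 or hr_window <= 0:
        raise ValueError("windows must be positive")
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must lie in (0, 1]")
    n = len(beats)
    counts = neighbor_counts(beats.times, beats.hr, time_window, hr_window)
    k = int(np.ceil(keep_fraction * n))
    cutoff = np.sort(counts)[::-1][k - 1]
    mask = counts >= cutoff
    return BeatSeries(times=beats.times[mask], hr=beats.hr[mask],
                      r_times=None, diagnostic=beats.diagnostic)


def remove_outliers(beats: BeatSeries,
                    hr_min: float = HR_MIN_DEFAULT,
                    hr_max: float = HR_MAX_DEFAULT) -> BeatSeries:
    """Drop beats outside the physiological window [hr_min, hr_max] bpm."""
    if hr_min <= 0 or hr_max <= 0 or hr_min >= hr_max:
        raise ValueError("need 0 < hr_min < hr_max")
    if beats.is_empty:
        return beats
    mask = (beats.hr >= hr_min) & (beats.hr <= hr_max)
    n_removed = int(np.sum(~mask))
    note = beats.diagnostic
    if n_removed:
        note = (note + "; " if note else "") + f"{n_removed} outlier(s) removed"
    return BeatSeries(times=beats.times[mask], hr=beats.hr[mask],
                      r_times=None, diagnostic=note)


def resample_hr(beats: BeatSeries, rate: float = 5.0,
                max_gap: float = 2.0,
                meta: SessionMeta | None = None) -> HeartRateSeries:
    """Place instantaneous heart rate on a uniform grid by zero-order hold.

    Each grid point takes the most recent inter-beat value; grid points
    more than ``max_gap`` seconds after the last retained beat (or before
    the first) are emitted as NaN with quality ``"gap"``.
    """
    if len(beats) < 2:
        raise ValueError("need at least two beats to resample")
    t0, t1 = beats.times[0], beats.times[-1]
    step = 1.0 / rate
    grid = np.arange(np.ceil(t0 / step) * step, t1 + step / 2, step)
    idx = np.searchsorted(beats.times, grid + 1e-12) - 1
    hr = np.full(len(grid), np.nan)
    quality = np.full(len(grid), "gap", dtype=object)
    valid = idx >= 0
    age = np.where(valid, grid - beats.times[np.clip(idx, 0, None)], np.inf)
    ok = valid & (age <= max_gap)
    hr[ok] = beats.hr[idx[ok]]
    quality[ok] = "ok"
    return HeartRateSeries(times=grid, hr=hr, quality=np.asarray(quality),
                           meta=meta or SessionMeta())


def extract_heart_rate(ecg: ECGTrace,
                       heave_dynamic: np.ndarray | None = None,
                       time_window: float = 2.0,
                       hr_window: float = 20.0,
                       keep_fraction: float = 0.95,
                       hr_min: float = HR_MIN_DEFAULT,
                       hr_max: float = HR_MAX_DEFAULT,
                       rate: float = 5.0,
                       max_gap: float = 2.0) -> HeartRateSeries:
    """Full chain: detect -> density filter -> outlier window -> 5 Hz grid."""
    beats = detect_qrs(ecg, heave_dynamic=heave_dynamic, hr_max=hr_max)
    if beats.is_empty:
        raise ValueError(f"no usable beats: {beats.diagnostic or 'empty'}")
    beats = density_filter(beats, time_window, hr_window, keep_fraction)
    beats = remove_outliers(beats, hr_min, hr_max)
    return resample_hr(beats, rate=rate, max_gap=max_gap, meta=ecg.meta)
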