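"""Flap/glide classification and the merged 1 Hz session table.

Flapping drives a large oscillation on the dynamic heave axis; gliding
leaves it nearly flat.  An instant is a glide candidate when
|dynamic heave| is below a 300 mg threshold, and a candidate run counts as
gliding only if it lasts at least one wingbeat (0.2 s) — shorter dips
(e.g. the zero-crossing dwells inside a wingbeat cycle) are relabeled
flapping.  The threshold applies to the DYNAMIC heave: the raw axis
carries ~1 g of gravity in level flight, which would make a raw-value rule
unsatisfiable.

The per-sample states are then merged with the 5 Hz heart-rate series and
1 Hz VeDBA series on the VeDBA timestamps, giving the final 1 Hz analysis
table, from which per-session gliding proportions and per-condition
summaries are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecg import HeartRateSeries
from .session import SessionMeta
from .study import FLAP_GLIDE_THRESHOLD_MG, MIN_GLIDE_S
from .vedba import VeDBASeries

FLAP = "flap"
GLIDE = "glide"

MERGED_COLUMNS = ["time_s", "hr_bpm", "hr_missing", "vedba_mg", "state",
                  "bird", "date", "flight_number", "logger_shape", "wind_angle"]


@dataclass
class FlightStateSeries:
    """Per-sample flap/glide labels plus the run-length segment list."""

    times: np.ndarray
    states: np.ndarray                      # "flap" | "glide" per sample
    segments: list = field(default_factory=list)  # (state, start_s, end_s)
    sampling_rate: float = 1600.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states)
        if len(self.times) != len(self.states):
            raise ValueError("times and states must align")

    def __len__(self) -> int:
        return len(self.states)

    def state_at(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous state at arbitrary times (nearest sample)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        pos = np.searchsorted(self.times, t)
        pos = np.clip(pos, 1, len(self.times) - 1)
        left, right = self.times[pos - 1], self.times[pos]
        take = np.where(np.abs(t - left) <= np.abs(right - t), pos - 1, pos)
        return self.states[take]


def _runs(mask: np.ndarray):
    """Maximal runs of equal value: yields (value, start_idx, stop_idx)."""
    n = len(mask)
    if n == 0:
        return
    change = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [n]))
    for s, e in zip(starts, stops):
        yield bool(mask[s]), int(s), int(e)


def classify_flap_glide(heave_dynamic_mg: np.ndarray,
                        sampling_rate: float,
                        threshold: float = FLAP_GLIDE_THRESHOLD_MG,
                        min_glide: float = MIN_GLIDE_S,
                        start_time: float = 0.0) -> FlightStateSeries:
    """Label each sample flap or glide from the dynamic heave axis (mg).

    Candidate glide = maximal runs with |heave| < threshold; runs shorter
    than ``min_glide`` seconds are relabeled flap in a single pass (no
    iterative merging).
    """
    hv = np.abs(np.asarray(heave_dynamic_mg, dtype=float))
    if len(hv) == 0:
        raise ValueError("empty heave series")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if sampling_rate <= 0:
        raise ValueError("sampling rate must be positive")

    below = hv < threshold
    states = np.full(len(hv), FLAP, dtype=object)
    min_samples = min_glide * sampling_rate
    for is_glide, s, e in _runs(below):
        if is_glide and (e - s) >= min_samples:
            states[s:e] = GLIDE

    times = start_time + np.arange(len(hv)) / sampling_rate
    segments = []
    for _, s, e in _runs(states == GLIDE):
        seg_state = str(states[s])
        segments.append((seg_state, times[s], start_time + e / sampling_rate))
    return FlightStateSeries(times=times, states=np.asarray(states),
                             segments=segments, sampling_rate=sampling_rate)


def merge_streams(hr: HeartRateSeries, vedba: VeDBASeries,
                  states: FlightStateSeries,
                  meta: SessionMeta | None = None) -> pd.DataFrame:
    """Build the final 1 Hz analysis table, one row per VeDBA timestamp.

    Heart rate is the 5 Hz value at the 1 Hz timestamp (its grid contains
    the integer seconds); the state is the instantaneous state at that
    timestamp.  Rows without usable heart rate are flagged, not dropped.
    """
    meta = meta or vedba.meta
    if len(vedba) == 0:
        raise ValueError("empty VeDBA series")
    t = vedba.times
    if t[0] > hr.times[-1] or t[-1] < hr.times[0]:
        raise ValueError("heart-rate and VeDBA series do not overlap in time")

    # exact 5 Hz -> 1 Hz lookup with a half-step tolerance
    hr_vals = np.full(len(t), np.nan)
    pos = np.searchsorted(hr.times, t)
    pos = np.clip(pos, 1, len(hr.times) - 1)
    left, right = hr.times[pos - 1], hr.times[pos]
    take = np.where(np.abs(t - left) <= np.abs(right - t), pos - 1, pos)
    close = np.abs(hr.times[take] - t) <= 0.5 / 5.0
    good = close & (np.asarray(hr.quality[take]) == "ok")
    hr_vals[good] = hr.hr[take[good]]

    df = pd.DataFrame({
        "time_s": t,
        "hr_bpm": hr_vals,
        "hr_missing": ~good,
        "vedba_mg": vedba.vedba,
        "state": states.state_at(t),
    })
    for key, val in meta.as_dict().items():
        df[key] = val
    return df[MERGED_COLUMNS]


def gliding_proportion(session: pd.DataFrame) -> float:
    """Fraction of 1 Hz rows labeled glide."""
    if len(session) == 0:
        raise ValueError("empty session")
    return float(np.mean(session["state"].to_numpy() == GLIDE))


def condition_summary(sessions: list[pd.DataFrame]) -> pd.DataFrame:
    """Per (logger_shape x wind_angle) campaign overview.

    Columns: flights per bird, total recorded seconds, mean heart rate over
    non-missing rows, mean VeDBA, and the pooled gliding proportion.
    """
    if not sessions:
        raise ValueError("no sessions")
    big = pd.concat(sessions, ignore_index=True)
    bad_shape = set(big["logger_shape"]) - {"cube", "drop"}
    bad_angle = set(big["wind_angle"]) - {"+2", "+6"}
    if bad_shape or bad_angle:
        raise ValueError(f"unknown condition labels: {bad_shape | bad_angle}")

    rows = []
    for (shape, angle), grp in big.groupby(["logger_shape", "wind_angle"],
                                           sort=True):
        flights = (grp.groupby("bird")[["date", "flight_number"]]
                      .apply(lambda g: len(g.drop_duplicates())))
        rows.append({
            "logger_shape": shape,
            "wind_angle": angle,
            **{f"n_flights_{b}": int(flights.get(b, 0))
               for b in sorted(big["bird"].unique())},
            "recorded_seconds": int(len(grp)),
            "mean_hr_bpm": float(grp["hr_bpm"].mean()),
            "mean_vedba_mg": float(grp["vedba_mg"].mean()),
            "gliding_proportion": float(np.mean(grp["state"] == GLIDE)),
        })
    return pd.DataFrame(rows)


def flap_glide_summary(sessions: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean and SD of heart rate and VeDBA grouped by flight state.

    A state absent from the data yields a row of NaNs (reported missing,
    never zero).
    """
    if not sessions:
        raise ValueError("no sessions")
    big = pd.concat(sessions, ignore_index=True)
    rows = []
    for state in (FLAP, GLIDE):
        grp = big[big["state"] == state]
        rows.append({
            "state": state,
            "n_seconds": int(len(grp)),
            "mean_hr_bpm": float(grp["hr_bpm"].mean()) if len(grp) else np.nan,
            "sd_hr_bpm": float(grp["hr_bpm"].std()) if len(grp) else np.nan,
            "mean_vedba_mg": float(grp["vedba_mg"].mean()) if len(grp) else np.nan,
            "sd_vedba_mg": float(grp["vedba_mg"].std()) if len(grp) else np.nan,
        })
    return pd.DataFrame(rows)
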