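"""CSV readers and writers for the pipeline's on-disk formats.

Time-series files are plain CSV with a ``time_s`` column (seconds on the
session clock); GPS files follow the Movebank column convention
(``timestamp``, ``location-lat``, ``location-long``,
``individual-local-identifier``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ecg import ECGTrace, HeartRateSeries
from .gps import GPSTrack
from .session import SessionMeta
from .vedba import AccelTrace, VeDBASeries

MOVEBANK_COLS = {
    "timestamp": "timestamp",
    "location-lat": "lat",
    "location-long": "lon",
    "individual-local-identifier": "bird",
}


def write_ecg_csv(trace: ECGTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "ecg_mV": trace.samples}) \
        .to_csv(path, index=False)


def read_ecg_csv(path, sampling_rate: float | None = None,
                 meta: SessionMeta | None = None) -> ECGTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if sampling_rate is None:
        if len(t) < 2:
            raise ValueError("cannot infer sampling rate from one sample")
        sampling_rate = 1.0 / float(np.median(np.diff(t)))
    return ECGTrace(samples=df["ecg_mV"].to_numpy(dtype=float),
                    sampling_rate=sampling_rate, start_time=float(t[0]),
                    meta=meta or SessionMeta())


def write_accel_csv(trace: AccelTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "ax_g": trace.surge,
                  "ay_g": trace.sway, "az_g": trace.heave}) \
        .to_csv(path, index=False)


def read_accel_csv(path, sampling_rate: float | None = None,
                   meta: SessionMeta | None = None) -> AccelTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if sampling_rate is None:
        if len(t) < 2:
            raise ValueError("cannot infer sampling rate from one sample")
        sampling_rate = 1.0 / float(np.median(np.diff(t)))
    return AccelTrace(surge=df["ax_g"].to_numpy(dtype=float),
                      sway=df["ay_g"].to_numpy(dtype=float),
                      heave=df["az_g"].to_numpy(dtype=float),
                      sampling_rate=sampling_rate, start_time=float(t[0]),
                      meta=meta or SessionMeta())


def write_hr_csv(hr: HeartRateSeries, path) -> None:
    pd.DataFrame({"time_s": hr.times, "hr_bpm": hr.hr,
                  "quality": hr.quality}).to_csv(path, index=False)


def read_hr_csv(path, meta: SessionMeta | None = None) -> HeartRateSeries:
    df = pd.read_csv(path)
    return HeartRateSeries(times=df["time_s"].to_numpy(dtype=float),
                           hr=df["hr_bpm"].to_numpy(dtype=float),
                           quality=df["quality"].to_numpy(),
                           meta=meta or SessionMeta())


def write_vedba_csv(v: VeDBASeries, path) -> None:
    pd.DataFrame({"time_s": v.times, "vedba_mg": v.vedba}).to_csv(path, index=False)


def read_vedba_csv(path, meta: SessionMeta | None = None) -> VeDBASeries:
    df = pd.read_csv(path)
    return VeDBASeries(times=df["time_s"].to_numpy(dtype=float),
                       vedba=df["vedba_mg"].to_numpy(dtype=float),
                       meta=meta or SessionMeta())


def write_gps_csv(track: GPSTrack, path) -> None:
    """Movebank-style GPS CSV (ISO-8601 UTC timestamps)."""
    f = track.fixes
    out = pd.DataFrame({
        "timestamp": pd.to_datetime(f["timestamp"], utc=True)
                       .dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
        "location-lat": f["lat"],
        "location-long": f["lon"],
        "individual-local-identifier": track.bird,
    })
    out.to_csv(path, index=False)


def read_gps_csv(path, attachment: str = "") -> list[GPSTrack]:
    """Read a Movebank-style CSV; one GPSTrack per individual."""
    df = pd.read_csv(path).rename(columns=MOVEBANK_COLS)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    tracks = []
    for bird, grp in df.groupby("bird", sort=True):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        tracks.append(GPSTrack(bird=str(bird), attachment=attachment,
                               fixes=grp[["timestamp", "lat", "lon"]]))
    return tracks


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
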