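"""Synthetic ECG, acceleration, and GPS generators with ground truth.

Every generator returns its latent truth alongside the signal — R-peak
times, per-sample flight-state labels, per-day movement targets — so the
downstream pipeline's recovery can be asserted exactly.  All randomness
flows from an explicit integer seed, and identical seeds plus parameters
give bit-identical output.

What is emulated
----------------
* **Acceleration**: a 1 g gravity component on the heave axis with a slow
  (< 0.2 Hz) sinusoidal orientation drift, plus an oscillation at the
  wingbeat frequency during flapping bouts (dynamic amplitude well above
  the 300 mg flap/glide threshold) and a small residual during gliding,
  plus white sensor noise.  Clipped to the +/-8 g logger range.
* **ECG**: Gaussian-shaped QRS pulses whose instantaneous rate follows a
  piecewise-linear heart-rate profile, plus baseline wander, white noise,
  and a motion artifact proportional to |dynamic heave| (flapping shakes
  the electrodes).  Clipped to the +/-6 mV logger range.
* **GPS**: day-by-day itineraries; migration days advance toward the
  breeding site along the great circle with the prescribed path length,
  stopover days fly an out-and-back foraging loop; per-fix isotropic
  jitter (default sigma 15 m) emulates receiver noise.

Not emulated: aerodynamics, realistic PQRST morphology, altitude, or
weather-driven route variation (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as date_cls
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from . import study
from .gps import GPSTrack, destination_point, initial_bearing_deg
from .session import SessionMeta
from .vedba import AccelTrace, dynamic_heave

# ---------------------------------------------------------------------------
# flight plans -> acceleration
# ---------------------------------------------------------------------------

FLAP = "flap"
GLIDE = "glide"


@dataclass
class Segment:
    """One bout of a flight plan."""

    state: str                   # "flap" | "glide"
    duration: float              # s
    wingbeat_hz: float = 5.0     # oscillation frequency during flapping
    heave_amplitude_mg: float = 850.0  # peak dynamic heave


@dataclass
class FlightPlan:
    """Scripted sequence of flapping and gliding bouts.

    Flap segments must exceed the 300 mg classification threshold and
    carry a positive wingbeat frequency; glide segments must stay below
    it.
    """

    segments: list[Segment]
    sampling_rate: float = 1600.0
    seed: int = 0
    noise_sd_g: float = 0.01         # white sensor noise per axis
    drift_deg: float = 10.0          # orientation-drift tilt amplitude
    drift_hz: float = 0.1            # orientation-drift frequency (< 0.2 Hz)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("plan needs at least one segment")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        for seg in self.segments:
            if seg.state not in (FLAP, GLIDE):
                raise ValueError(f"unknown state {seg.state!r}")
            if seg.duration <= 0:
                raise ValueError("segment durations must be positive")
            if seg.state == FLAP:
                if seg.heave_amplitude_mg <= study.FLAP_GLIDE_THRESHOLD_MG:
                    raise ValueError("flap amplitude must exceed 300 mg")
                if seg.wingbeat_hz <= 0:
                    raise ValueError("flap wingbeat frequency must be positive")
            else:
                if seg.heave_amplitude_mg >= study.FLAP_GLIDE_THRESHOLD_MG:
                    raise ValueError("glide amplitude must stay below 300 mg")

    @property
    def duration(self) -> float:
        return sum(seg.duration for seg in self.segments)


@dataclass
class AccelSynthesis:
    """Generated acceleration plus its ground truth."""

    trace: AccelTrace
    states: np.ndarray           # per-sample truth labels


def generate_accel(plan: FlightPlan,
                   meta: SessionMeta | None = None) -> AccelSynthesis:
    """Synthesize a tri-axial acceleration trace from a flight plan.

    Heave = gravity (tilting slowly by ``drift_deg`` at ``drift_hz``)
    + per-segment wingbeat oscillation + white noise; surge carries the
    tilt complement and a small fraction of the wingbeat; sway is noise
    only.  Samples are clipped to +/-8 g, but amplitudes that would place
    the clean signal outside the logger range are rejected outright.
    """
    fs = plan.sampling_rate
    rng = np.random.default_rng(plan.seed)
    n = int(round(plan.duration * fs))
    t = np.arange(n) / fs

    worst = 1.0 + max(s.heave_amplitude_mg for s in plan.segments) / 1000.0
    if worst + 5 * plan.noise_sd_g > study.ACCEL_RANGE_G:
        raise ValueError("plan amplitude exceeds the +/-8 g logger range")

    states = np.empty(n, dtype=object)
    osc = np.zeros(n)
    start = 0.0
    for seg in plan.segments:
        i0 = int(round(start * fs))
        i1 = min(int(round((start + seg.duration) * fs)), n)
        states[i0:i1] = seg.state
        # random initial phase per bout: real wingbeats are not locked to
        # the logger clock, and without it the 1 Hz decimation would keep
        # sampling the same point of the cycle
        phase = rng.uniform(0.0, 2 * np.pi)
        if seg.state == FLAP:
            amp = seg.heave_amplitude_mg / 1000.0
            osc[i0:i1] = amp * np.sin(
                2 * np.pi * seg.wingbeat_hz * (t[i0:i1] - start) + phase)
        elif seg.heave_amplitude_mg > 0:
            # residual glide vibration, low-frequency and sub-threshold
            amp = seg.heave_amplitude_mg / 1000.0
            osc[i0:i1] = amp * 0.5 * np.sin(
                2 * np.pi * 1.3 * (t[i0:i1] - start) + phase)
        start += seg.duration
    states[states == None] = plan.segments[-1].state  # noqa: E711 - rounding tail

    tilt = np.radians(plan.drift_deg) * np.sin(2 * np.pi * plan.drift_hz * t)
    gravity_heave = np.cos(tilt)
    gravity_surge = np.sin(tilt)

    noise = rng.normal(0.0, plan.noise_sd_g, size=(3, n)) if plan.noise_sd_g > 0 \
        else np.zeros((3, n))
    heave = np.clip(gravity_heave + osc + noise[2], -8.0, 8.0)
    surge = np.clip(gravity_surge + 0.25 * osc + noise[0], -8.0, 8.0)
    sway = np.clip(noise[1], -8.0, 8.0)

    trace = AccelTrace(surge=surge, sway=sway, heave=heave, sampling_rate=fs,
                       meta=meta or SessionMeta())
    return AccelSynthesis(trace=trace, states=np.asarray(states, dtype=object))


# ---------------------------------------------------------------------------
# heart-rate profiles -> ECG
# ---------------------------------------------------------------------------

@dataclass
class HRProfile:
    """Piecewise-linear instantaneous heart-rate profile plus noise model.

    ``breakpoints`` are (time s, heart rate bpm) pairs; rate is linearly
    interpolated between them and held constant outside.  ``qrs_width`` is
    the full width of the Gaussian R-pulse (~4 sigma).  ``artifact_gain``
    couples |dynamic heave| (g) into the trace (mV per g).
    """

    breakpoints: list[tuple[float, float]]
    qrs_width: float = 0.008
    qrs_amplitude: float = 2.0
    noise_sd: float = 0.0
    artifact_gain: float = 0.0
    baseline_mV: float = 0.0
    baseline_hz: float = 0.33
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.breakpoints:
            raise ValueError("profile needs at least one breakpoint")
        rates = [hr for _, hr in self.breakpoints]
        if min(rates) <= 60.0 or max(rates) >= 800.0:
            raise ValueError("heart rate must lie inside (60, 800) bpm")
        if not 0 < self.qrs_amplitude <= study.ECG_RANGE_MV:
            raise ValueError("QRS amplitude must fit the +/-6 mV range")
        if 60.0 / max(rates) < 3.0 * self.qrs_width:
            raise ValueError("RR interval under 3 x qrs_width: beats unresolvable")

    def rate_at(self, t: np.ndarray) -> np.ndarray:
        tp = np.array([b[0] for b in self.breakpoints], dtype=float)
        hp = np.array([b[1] for b in self.breakpoints], dtype=float)
        return np.interp(np.asarray(t, dtype=float), tp, hp)


@dataclass
class ECGSynthesis:
    """Generated ECG plus its ground-truth R-times."""

    trace: "ECGTrace"
    r_times: np.ndarray


def _r_times_from_profile(profile: HRProfile, duration: float,
                          fs: float) -> np.ndarray:
    """Beat times where the integrated instantaneous rate crosses k - 1/2."""
    t = np.arange(int(round(duration * fs)) + 1) / fs
    rate_hz = profile.rate_at(t) / 60.0
    phase = np.concatenate(([0.0], np.cumsum((rate_hz[1:] + rate_hz[:-1]) / 2.0 / fs)))
    n_beats = int(np.floor(phase[-1] + 0.5))
    if n_beats < 1:
        return np.array([])
    ks = np.arange(1, n_beats + 1) - 0.5
    return np.interp(ks, phase, t)


def generate_ecg(profile: HRProfile, accel: AccelTrace | None = None,
                 duration: float | None = None,
                 sampling_rate: float = 1600.0,
                 meta: SessionMeta | None = None) -> ECGSynthesis:
    """Synthesize an ECG trace following the heart-rate profile.

    If ``accel`` is given, the ECG shares its sampling rate and duration
    and picks up motion artifact ``artifact_gain * |dynamic heave|``.
    """
    from .ecg import ECGTrace

    if accel is not None:
        fs = accel.sampling_rate
        dur = accel.duration
    else:
        if duration is None:
            raise ValueError("need either an accel trace or a duration")
        fs, dur = sampling_rate, float(duration)

    rng = np.random.default_rng(profile.seed)
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    r_times = _r_times_from_profile(profile, dur, fs)

    ecg = np.zeros(n)
    sigma = profile.qrs_width / 4.0
    half = max(int(round(5 * sigma * fs)), 1)
    kernel_t = np.arange(-half, half + 1) / fs
    kernel = profile.qrs_amplitude * np.exp(-0.5 * (kernel_t / sigma) ** 2)
    for r in r_times:
        c = int(round(r * fs))
        s, e = c - half, c + half + 1
        ks, ke = max(-s, 0), len(kernel) - max(e - n, 0)
        s, e = max(s, 0), min(e, n)
        if s < e:
            ecg[s:e] += kernel[ks:ke]

    if profile.baseline_mV > 0:
        ecg += profile.baseline_mV * np.sin(2 * np.pi * profile.baseline_hz * t)
    if profile.artifact_gain > 0 and accel is not None:
        ecg += profile.artifact_gain * np.abs(dynamic_heave(accel))
    if profile.noise_sd > 0:
        ecg += rng.normal(0.0, profile.noise_sd, size=n)
    ecg = np.clip(ecg, -study.ECG_RANGE_MV, study.ECG_RANGE_MV)

    trace = ECGTrace(samples=ecg, sampling_rate=fs,
                     meta=meta or (accel.meta if accel is not None else SessionMeta()))
    return ECGSynthesis(trace=trace, r_times=r_times)


# ---------------------------------------------------------------------------
# itineraries -> GPS tracks
# ---------------------------------------------------------------------------

@dataclass
class DayPlan:
    """One itinerary day: a date, a target path length, and its truth label."""

    date: date_cls
    target_km: float
    day_type: str                # "migration" | "stopover"


@dataclass
class Itinerary:
    """Multi-day movement script between a start point and the breeding site."""

    days: list[DayPlan]
    start_location: tuple[float, float]       # (lat, lon), WGS84 degrees
    breeding_site: tuple[float, float]
    fixes_per_day: int = 52
    jitter_m: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fixes_per_day < 2:
            raise ValueError("need at least two fixes per day")
        for d in self.days:
            if d.day_type not in ("migration", "stopover"):
                raise ValueError(f"unknown day type {d.day_type!r}")
            if d.target_km < 0:
                raise ValueError("targets must be non-negative")
            if d.day_type == "migration" and d.target_km < study.MIGRATION_THRESHOLD_KM:
                raise ValueError("migration days need a target of at least 50 km")
            if d.day_type == "stopover" and d.target_km >= study.MIGRATION_THRESHOLD_KM:
                raise ValueError("stopover days must stay under 50 km")


@dataclass
class GPSSynthesis:
    """Generated track plus per-day ground truth."""

    track: GPSTrack
    truth: pd.DataFrame          # date, day_type, target_km


def generate_gps_track(it: Itinerary, bird: str = "bird",
                       attachment: str = "") -> GPSSynthesis:
    """Emit timestamped fixes realizing the itinerary.

    Migration days walk toward the breeding site along the great circle in
    equal steps summing to the target length; stopover days fly out on a
    random bearing for half the target and return.  Per-fix jitter is
    isotropic with sigma ``jitter_m``.  Fixes span 07:00-17:00 UTC so the
    civil date is unambiguous across the route's timezone.
    """
    rng = np.random.default_rng(it.seed)
    lat, lon = it.start_location
    blat, blon = it.breeding_site

    rows = []
    truth_rows = []
    for day in it.days:
        nfix = it.fixes_per_day
        nseg = nfix - 1
        step = day.target_km / nseg if nseg else 0.0
        t0 = datetime(day.date.year, day.date.month, day.date.day, 7, 0,
                      tzinfo=timezone.utc)
        stamps = [t0 + timedelta(seconds=i * 36000.0 / nseg) for i in range(nfix)]

        pts = [(lat, lon)]
        plat, plon = lat, lon
        if day.day_type == "migration":
            for _ in range(nseg):
                brg = initial_bearing_deg(plat, plon, blat, blon)
                plat, plon = destination_point(plat, plon, float(brg), step)
                pts.append((float(plat), float(plon)))
        else:
            out_brg = float(rng.uniform(0.0, 360.0))
            n_out = nseg // 2
            for i in range(nseg):
                brg = out_brg if i < n_out else (out_brg + 180.0) % 360.0
                plat, plon = destination_point(plat, plon, brg, step)
                pts.append((float(plat), float(plon)))

        pts = np.asarray(pts, dtype=float)
        if it.jitter_m > 0:
            deg_lat = it.jitter_m / 1000.0 / 111.195  # km per degree latitude
            jit = rng.normal(0.0, deg_lat, size=pts.shape)
            jit[:, 1] /= np.cos(np.radians(pts[:, 0]))
            pts = pts + jit

        for stamp, (fl, fo) in zip(stamps, pts):
            rows.append({"timestamp": stamp, "lat": fl, "lon": fo})
        truth_rows.append({"date": day.date, "day_type": day.day_type,
                           "target_km": day.target_km})
        if day.day_type == "migration":
            lat, lon = float(plat), float(plon)
        # stopover days end (up to jitter) where they started

    track = GPSTrack(bird=bird, attachment=attachment,
                     fixes=pd.DataFrame(rows))
    return GPSSynthesis(track=track, truth=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# wind-tunnel campaign presets
# ---------------------------------------------------------------------------

def condition_gliding_proportion(shape: str, angle: str, bird: str = "310") -> float:
    """Ground-truth gliding proportion for a wind-tunnel condition."""
    eff = study.GLIDING_EFFECTS
    p = eff["intercept"]
    if shape == "drop":
        p += eff["drop"]
    if angle == "+6":
        p += eff["wind6"]
    if shape == "drop" and angle == "+6":
        p += eff["drop_wind6"]
    if bird == "311":
        p += eff["bird311"]
    return float(np.clip(p, 0.02, 0.98))


def plan_for_proportion(glide_fraction: float, duration: float = 60.0,
                        cycle: float = 7.3, flap_amplitude_mg: float = 850.0,
                        glide_amplitude_mg: float = 50.0,
                        wingbeat_hz: float = 5.0, seed: int = 0,
                        sampling_rate: float = 1600.0) -> FlightPlan:
    """Alternating flap/glide plan whose glide share equals ``glide_fraction``.

    Built from repeated fixed-length cycles so every bout lasts >= 1 s,
    keeping comfortable dwell margins around the 300 mg threshold.  The
    default cycle length is deliberately non-integer so bout boundaries
    drift relative to the 1 Hz decimation grid instead of aliasing.
    """
    if not 0.0 <= glide_fraction <= 1.0:
        raise ValueError("glide_fraction must lie in [0, 1]")
    # snap to a whole number of cycles so the realized share is exact
    cycle = duration / max(round(duration / cycle), 1)
    glide_s = glide_fraction * cycle
    flap_s = cycle - glide_s
    segments: list[Segment] = []
    elapsed = 0.0
    while elapsed < duration - 1e-9:
        if flap_s > 1e-9:
            d = min(flap_s, duration - elapsed)
            segments.append(Segment(FLAP, d, wingbeat_hz, flap_amplitude_mg))
            elapsed += d
        if glide_s > 1e-9 and elapsed < duration - 1e-9:
            d = min(glide_s, duration - elapsed)
            segments.append(Segment(GLIDE, d, wingbeat_hz, glide_amplitude_mg))
            elapsed += d
    return FlightPlan(segments=segments, sampling_rate=sampling_rate, seed=seed)


def simulate_gliding_experiment(seed: int = 0, sigma: float = 0.03) -> pd.DataFrame:
    """Session-level gliding proportions for the wind-tunnel campaign.

    One row per flight session (26 in the default layout), with the
    session's gliding proportion drawn as the condition's ground-truth
    level plus N(0, sigma) session-to-session noise.  This is the design
    table the gliding-proportion OLS consumes.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (bird, shape, angle), n in study.WIND_TUNNEL_SESSIONS.items():
        p = condition_gliding_proportion(shape, angle, bird)
        for k in range(n):
            rows.append({
                "bird": bird, "logger_shape": shape, "wind_angle": angle,
                "session": k + 1,
                "gliding_proportion": float(np.clip(p + rng.normal(0.0, sigma),
                                                    0.0, 1.0)),
                "truth": p,
            })
    return pd.DataFrame(rows)


def simulate_distance_study(seed: int = 0) -> pd.DataFrame:
    """Bird-day daily distances for the spring-migration field study.

    37 birds (10 wing-loop, 27 leg-loop) contribute 1060 bird-days in the
    campaign's attachment split (332 / 728).  Each day's distance is drawn
    on the log10 scale from the random-intercept model truth
    (:data:`ibisflight.study.DISTANCE_MODEL_TRUTH`); roughly a third of
    days are migration days.  Returns a daily-summary-style table with
    columns ``bird, attachment, day_type, path_km``.
    """
    rng = np.random.default_rng(seed)
    truth = study.DISTANCE_MODEL_TRUTH

    def _spread(total: int, birds: int) -> list[int]:
        base = total // birds
        extra = total - base * birds
        return [base + (1 if i < extra else 0) for i in range(birds)]

    rows = []
    bird_id = 0
    for attachment, n_birds, n_days in (("wing_loop", study.N_WING_LOOP,
                                         study.N_DAYS_WING_LOOP),
                                        ("leg_loop", study.N_LEG_LOOP,
                                         study.N_DAYS_LEG_LOOP)):
        for per_bird in _spread(n_days, n_birds):
            bird_id += 1
            b = rng.normal(0.0, truth["bird_sd"])
            for _ in range(per_bird):
                mig = rng.random() < 0.35
                mean = (truth["intercept"]
                        + (truth["attachment_leg_loop"]
                           if attachment == "leg_loop" else 0.0)
                        + (truth["activity_migration"] if mig else 0.0)
                        + (truth["interaction"]
                           if mig and attachment == "leg_loop" else 0.0))
                log10_km = mean + b + rng.normal(0.0, truth["resid_sd"])
                rows.append({"bird": f"bird{bird_id:02d}",
                             "attachment": attachment,
                             "day_type": "migration" if mig else "stopover",
                             "path_km": float(10.0 ** log10_km)})
    return pd.DataFrame(rows)


@dataclass
class SessionSynthesis:
    """One fully synthesized wind-tunnel flight."""

    accel: AccelSynthesis
    ecg: ECGSynthesis
    meta: SessionMeta
    glide_fraction_truth: float
    hr_truth: dict               # state -> bpm


def synthesize_session(bird: str, shape: str, angle: str,
                       date: str = "2020-08-01", flight_number: int = 1,
                       duration: float = 60.0, seed: int = 0,
                       noise_sd_mV: float = 0.1,
                       artifact_gain: float = 0.3,
                       sampling_rate: float = 1600.0,
                       glide_fraction: float | None = None) -> SessionSynthesis:
    """Simulate one wind-tunnel flight under a campaign condition.

    The gliding share and mean heart rate come from the campaign presets
    for the (shape, angle) condition (``glide_fraction`` overrides the
    preset share, e.g. to add session-to-session variation); heart rate
    runs higher during flapping bouts than gliding bouts, with the
    duration-weighted mean matching the condition level.
    """
    meta = SessionMeta(bird=bird, date=date, flight_number=flight_number,
                       logger_shape=shape, wind_angle=angle)
    p = (condition_gliding_proportion(shape, angle, bird)
         if glide_fraction is None else float(np.clip(glide_fraction, 0.02, 0.98)))
    plan = plan_for_proportion(p, duration=duration, seed=seed,
                               sampling_rate=sampling_rate)
    acc = generate_accel(plan, meta=meta)

    mean_hr = study.CONDITION_MEAN_HR_BPM[(shape, angle)]
    # flap/glide split around the condition mean, weighted back to it
    hr_glide = mean_hr - 30.0 * (1 - p)
    hr_flap = mean_hr + 30.0 * p
    bps = []
    start = 0.0
    for seg in plan.segments:
        level = hr_flap if seg.state == FLAP else hr_glide
        bps.append((start + 1e-3, level))
        bps.append((start + seg.duration - 1e-3, level))
        start += seg.duration
    profile = HRProfile(breakpoints=bps, noise_sd=noise_sd_mV,
                        artifact_gain=artifact_gain, baseline_mV=0.1,
                        seed=seed + 1)
    ecg = generate_ecg(profile, accel=acc.trace, meta=meta)
    return SessionSynthesis(accel=acc, ecg=ecg, meta=meta,
                            glide_fraction_truth=p,
                            hr_truth={FLAP: hr_flap, GLIDE: hr_glide})
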