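"""Study-design constants for the Northern Bald Ibis flight campaigns.

Two campaigns are emulated by :mod:`ibisflight.synthetic`:

* a wind-tunnel experiment in which two trained birds flew under four
  conditions crossing logger housing shape (aerodynamic ``drop`` vs
  non-aerodynamic ``cube``) with outlet-nozzle wind angle (``+2`` degrees
  horizontal flow vs ``+6`` degrees updraft), carrying a combined
  ECG/accelerometer logger;
* a spring-migration field study of free-flying birds carrying GPS tags
  attached either by a wing-loop harness (upper back) or a leg-loop
  harness (lower back).

The numbers collected here are the design constants of those campaigns
(device masses, sample sizes, per-condition physiological levels) and are
used as the default parameters of the synthetic-data generators, so that
simulated data carry the statistical structure the downstream pipeline
assumes.
"""

from __future__ import annotations

# --- device masses (grams) -------------------------------------------------

#: ECG/accelerometer logger unit incl. wires, electrodes, battery, harness
#: and baseplate.
LOGGER_UNIT_G = 15.94
#: 3D-printed aerodynamic (drop-shaped) housing.
DROP_COVER_G = 18.3
#: 3D-printed non-aerodynamic (cube-shaped) housing; the drop cover is
#: ballasted to this mass so both conditions carry the same load.
CUBE_COVER_G = 22.4
#: Solar GPS tag incl. harness used in the field study.
GPS_TAG_G = 25.0
#: Mean body mass of the study birds.
MEAN_BODY_MASS_G = 1300.0

# --- sensor ranges ---------------------------------------------------------

ECG_SAMPLING_HZ = 1600.0
ECG_RANGE_MV = 6.0       # logger records -6..+6 mV
ACCEL_RANGE_G = 8.0      # tri-axial accelerometer records -8..+8 g

# --- analysis constants ----------------------------------------------------

#: |dynamic heave| threshold separating flapping from gliding (milli-g).
FLAP_GLIDE_THRESHOLD_MG = 300.0
#: Minimum glide duration: one wingbeat period (seconds).
MIN_GLIDE_S = 0.2
#: Daily path length at or above which a day counts as a migration day (km).
MIGRATION_THRESHOLD_KM = 50.0

# --- wind-tunnel campaign layout -------------------------------------------

LOGGER_SHAPES = ("cube", "drop")
WIND_ANGLES = ("+2", "+6")
WIND_TUNNEL_BIRDS = ("310", "311")

#: Per-condition mean heart rate (bpm) used by the synthetic campaign,
#: keyed by (logger_shape, wind_angle).  The ordering (cube+2 highest,
#: drop+6 lowest) reflects that an aerodynamic housing and an updraft both
#: lower the energetic cost of flight.
CONDITION_MEAN_HR_BPM = {
    ("cube", "+2"): 461.0,
    ("drop", "+2"): 443.0,
    ("cube", "+6"): 414.0,
    ("drop", "+6"): 335.0,
}

#: Per-condition gliding proportion used by the synthetic campaign.
#: Built from a reference level of 0.280 (cube, +2) plus additive effects:
#: drop shape +0.085, +6 degree updraft +0.279, shape-by-angle interaction
#: +0.099 — so the drop/+6 condition glides ~0.74 of the time while
#: cube/+2 glides ~0.28.
GLIDING_EFFECTS = {
    "intercept": 0.280,
    "drop": 0.085,
    "wind6": 0.279,
    "drop_wind6": 0.099,
    "bird311": -0.062,
}

#: Flights per (bird, condition) in the wind-tunnel campaign; a session is
#: one observation in the gliding-proportion model (26 total).
WIND_TUNNEL_SESSIONS = {
    ("310", "cube", "+2"): 3,
    ("310", "drop", "+2"): 4,
    ("310", "cube", "+6"): 3,
    ("310", "drop", "+6"): 3,
    ("311", "cube", "+2"): 4,
    ("311", "drop", "+2"): 3,
    ("311", "cube", "+6"): 3,
    ("311", "drop", "+6"): 3,
}

# --- field-study layout ----------------------------------------------------

N_BIRDS_FIELD = 37
N_WING_LOOP = 10
N_LEG_LOOP = 27
#: bird-days entering the distance model, by attachment.
N_DAYS_LEG_LOOP = 728
N_DAYS_WING_LOOP = 332
#: Mean GPS fixes per day, by attachment.
FIXES_PER_DAY = {"wing_loop": 82, "leg_loop": 52}

#: Generator truth for the log10(daily distance, km) mixed model:
#: intercept at the wing-loop/stopover reference, additive effects of
#: leg-loop attachment and migration-day activity, their interaction, and
#: the variance components (between-bird and residual SD on the log10
#: scale).
DISTANCE_MODEL_TRUTH = {
    "intercept": 1.588,
    "attachment_leg_loop": 0.039,
    "activity_migration": 0.449,
    "interaction": 0.001,
    "bird_sd": 0.004,
    "resid_sd": 0.063,
}

#: Mean daily distance on migration days, by attachment (km): leg-loop
#: birds cover more ground per day than wing-loop birds.
MEAN_MIGRATION_KM_PER_DAY = {"leg_loop": 130.0, "wing_loop": 113.0}
#: Mean daily distance on stopover days, by attachment (km).
MEAN_STOPOVER_KM_PER_DAY = {"leg_loop": 17.7, "wing_loop": 16.6}


def total_carried_mass(logger_g: float = LOGGER_UNIT_G,
                       cover_g: float = CUBE_COVER_G) -> float:
    """Total mass carried during a wind-tunnel session: logger unit + housing."""
    return logger_g + cover_g


def relative_load_percent(device_g: float,
                          body_mass_g: float = MEAN_BODY_MASS_G) -> float:
    """Device mass as a percentage of body mass (the '3 % rule' quantity)."""
    if body_mass_g <= 0:
        raise ValueError("body mass must be positive")
    return 100.0 * device_g / body_mass_g
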