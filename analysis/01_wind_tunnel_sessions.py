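#!/usr/bin/env python
"""Simulate the wind-tunnel campaign and run the full signal pipeline.

Generates every flight session of the 2 birds x (cube|drop) x (+2|+6)
design — synchronized ECG and tri-axial acceleration at 1600 Hz — then
extracts the 5 Hz heart rate, the 1 Hz VeDBA, the flap/glide states, and
merges them into the 1 Hz session tables.  Writes:

    results/sessions_1hz.csv        all merged 1 Hz rows
    results/session_gliding.csv     per-session gliding proportions
    results/condition_summary.csv   per-condition campaign overview
    results/flap_glide_summary.csv  HR/VeDBA by flight state
"""

import numpy as np
import pandas as pd

from ibisflight import ecg, segmentation, study, synthetic, vedba
from ibisflight.io import ensure_dir

SEED = 20200801
SESSION_S = 60.0            # per-flight duration used for the simulation
GLIDE_JITTER_SD = 0.03      # session-to-session spread of the gliding share

out = ensure_dir("results")
rng = np.random.default_rng(SEED)

merged_all, session_rows = [], []
k = 0
for (bird, shape, angle), n_sessions in study.WIND_TUNNEL_SESSIONS.items():
    for s in range(n_sessions):
        k += 1
        p_truth = synthetic.condition_gliding_proportion(shape, angle, bird)
        p_session = p_truth + rng.normal(0.0, GLIDE_JITTER_SD)
        sess = synthetic.synthesize_session(
            bird, shape, angle, date=f"2020-08-{(k % 14) + 1:02d}",
            flight_number=s + 1, duration=SESSION_S,
            seed=int(rng.integers(2 ** 31)), glide_fraction=p_session)

        heave = vedba.dynamic_heave(sess.accel.trace)
        hr = ecg.extract_heart_rate(sess.ecg.trace, heave_dynamic=heave)
        v = vedba.vedba_1hz(sess.accel.trace)
        states = segmentation.classify_flap_glide(
            heave * 1000.0, sess.accel.trace.sampling_rate)
        merged = segmentation.merge_streams(hr, v, states, meta=sess.meta)
        merged_all.append(merged)
        session_rows.append({
            "bird": bird, "logger_shape": shape, "wind_angle": angle,
            "session": s + 1,
            "gliding_proportion": segmentation.gliding_proportion(merged),
            "gliding_truth": sess.glide_fraction_truth,
            "mean_hr_bpm": float(merged["hr_bpm"].mean()),
        })

pd.concat(merged_all, ignore_index=True).to_csv(out / "sessions_1hz.csv",
                                                index=False)
sessions = pd.DataFrame(session_rows)
sessions.to_csv(out / "session_gliding.csv", index=False)

summary = segmentation.condition_summary(merged_all)
summary.to_csv(out / "condition_summary.csv", index=False)
fg = segmentation.flap_glide_summary(merged_all)
fg.to_csv(out / "flap_glide_summary.csv", index=False)

print(f"{len(sessions)} sessions, {sum(len(m) for m in merged_all)} merged "
      "1 Hz rows\n")
print("Per-condition overview (mean HR should fall cube+2 > drop+2 > "
      "cube+6 > drop+6,\ngliding proportion the reverse):")
print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nBy flight state (flapping costs more and shakes the body harder):")
print(fg.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
err = (sessions["gliding_proportion"] - sessions["gliding_truth"]).abs()
print(f"\nmeasured vs generated gliding share: max |error| {err.max():.3f} "
      "(includes the intended session jitter)")
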