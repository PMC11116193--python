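#!/usr/bin/env python
"""Fit the gliding-proportion regression over the simulated campaign.

Reads the per-session gliding proportions measured end-to-end by
01_wind_tunnel_sessions.py and fits the treatment-coded OLS

    gliding ~ logger_shape * wind_angle + bird

with cube / +2 degrees / bird 310 as reference levels.  Writes the
coefficient table to results/gliding_ols.csv and reports how the fitted
effects compare with the generator's truth.
"""

import pandas as pd

from ibisflight import models, study
from ibisflight.io import ensure_dir

out = ensure_dir("results")
sessions = pd.read_csv(out / "session_gliding.csv",
                       dtype={"bird": str, "logger_shape": str,
                              "wind_angle": str})

X, y, names = models.build_design(sessions,
                                  models.GLIDING_PRESET["response"],
                                  models.GLIDING_PRESET["factors"],
                                  models.GLIDING_PRESET["interactions"])
fit = models.fit_ols(X, y, names)
table = fit.to_frame()
table.to_csv(out / "gliding_ols.csv", index=False)

eff = study.GLIDING_EFFECTS
truth = {"Intercept": eff["intercept"], "logger_shape[drop]": eff["drop"],
         "wind_angle[+6]": eff["wind6"], "bird[311]": eff["bird311"],
         "logger_shape[drop]:wind_angle[+6]": eff["drop_wind6"]}
table = table.assign(truth=[truth[t] for t in table["term"]])

f, df1, df2 = fit.fstat
print(f"n = {fit.n_obs} sessions; R^2 = {fit.r2:.3f}, "
      f"F({df1}, {df2}) = {f:.1f}\n")
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
within = all(abs(r.estimate - r.truth) < 3 * r.se for r in table.itertuples())
print("\nall coefficients within 3 SE of generator truth:", within)
print("Interpretation: the drop-shaped housing raises the gliding share, "
      "the +6 degree\nupdraft raises it much more, and the two effects "
      "reinforce each other (positive\ninteraction) — an aerodynamic housing "
      "matters most when gliding is possible at all.")
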