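#!/usr/bin/env python
"""Pseudopopulation decoding of the three spatial variables.

Builds pseudopopulations (2 folds x 32 pseudo-trials per condition, neurons
bootstrapped) from a synthetic sequentially-tuned population, decodes the
(x, y) coordinates of start position, movement direction and target position
from 4 principal components at the four key time windows, and computes the
direction-vs-target error difference in sliding windows around the go sound.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from egoallo.decoding import (
    build_pseudopopulation,
    chance_error,
    decode_window,
    delta_error_timecourse,
)
from egoallo.selectivity import KEY_WINDOWS
from egoallo.simulate import generate_population

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

trials, neurons = generate_population(
    {"start": 40, "direction": 40, "target": 40, "none": 10},
    design="reference", n_trials=480, seed=41,
)

rows = []
for var in ("start", "direction", "target"):
    for wname, window in KEY_WINDOWS.items():
        errs = []
        for s in range(10):
            pp = build_pseudopopulation(trials, neurons, var, seed=s)
            errs.append(decode_window(pp, window).mean_error)
        rows.append({"variable": var, "window": wname,
                     "mean_error_mm": np.mean(errs),
                     "sd_error_mm": np.std(errs),
                     "chance_mm": chance_error(pp)})
tab = pd.DataFrame(rows)
tab.to_csv(OUT / "decoding_errors.csv", index=False)
print(tab.pivot_table(index="window", columns="variable",
                      values="mean_error_mm").round(1))
print(f"(chance level ~{tab.chance_mm.iloc[0]:.0f} mm; "
      f"port radius is 11 mm)")

delta = delta_error_timecourse(
    trials, neurons, ("direction", "target"), n_pseudo=20,
    align="t_go", t_range=(-0.3, 0.6), step=0.15, n_shuffle=2000,
)
delta.to_csv(OUT / "delta_direction_target.csv", index=False)
at_go = delta.iloc[(delta.t - 0.3).abs().argmin()]
print(f"\ndirection-vs-target delta at go+0.3 s: "
      f"{at_go.mean_delta:+.1f} mm (p = {at_go.p_perm:.2g}; negative means "
      f"direction decodes better)")
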