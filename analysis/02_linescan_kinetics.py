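#!/usr/bin/env python
"""Sensor activation kinetics from 550-Hz dual-channel line scans.

Simulates 50 trials with mono-exponential membrane activation at
τ = 596 ms and 10% noise, applies red-dye latency gating, membrane-pixel
classification, low-pass filtering and one-phase exponential fitting, and
reports the across-trial mean activation constant.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fluorkit.linescan import (classify_membrane_pixels, dye_onset_latency,
                               fit_pixel_taus)
from fluorkit.synth import gen_linescan

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 1

rows = []
for k in range(50):
    rec, truth = gen_linescan(SEED * 1000 + k, n_pixels=10, tau=0.596,
                              noise_sd_frac=0.1)
    cmap = classify_membrane_pixels(rec, (0.0, 1.0), (3.0, 5.0))
    latency = dye_onset_latency(rec.red.mean(axis=0), rec.sampling_rate)
    fits, tau_bar, gate = fit_pixel_taus(rec, cmap, ligand_onset=1.0)
    rows.append({"trial": k, "dye_latency_ms": latency * 1e3,
                 "gate_passed": gate,
                 "n_membrane": len(cmap.membrane_indices),
                 "tau_bar_ms": tau_bar * 1e3 if gate else np.nan})
df = pd.DataFrame(rows)
df.to_csv(OUT / "linescan_kinetics.csv", index=False)

mean_tau = df.loc[df.gate_passed, "tau_bar_ms"].mean()
print(f"{int(df.gate_passed.sum())}/50 trials passed the <50 ms dye gate; "
      f"mean tau-bar {mean_tau:.0f} ms (truth 596 ms)")
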