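# fluorkit

Analysis pipelines for recordings made with GPCR-based fluorescent
neuropeptide sensors — the class of probes built by inserting a
circularly permuted GFP into a receptor (here an orexin/OX2R-based
sensor), whose fluorescence reports ligand binding as a fractional
change ΔF/F₀ = (F(t) − F₀)/F₀.

The package covers the full characterisation chain such a sensor goes
through, for experimenters who need the exact printed protocols as
reusable, tested code:

* **in vitro**: ten-point-baseline ΔF/F₀ quantification and
  dose–response affinity via the four-parameter logistic
  y = bottom + (top − bottom)/(1 + (EC₅₀/x)^h);
* **activation kinetics**: 550-Hz dual-channel line scans with red-dye
  arrival gating (<50 ms to 85% rise) and one-phase exponential fits
  y = offset + A(1 − e^(−t/τ));
* **fiber photometry**: stimulation-trial processing (100-ms binning,
  Savitzky–Golay smoothing, median-anchored linear detrend, baseline
  z-scoring, laser-on peak, rise/decay τ fits), event-locked
  comparisons, and sleep-state transition deltas from hypnograms;
* **locomotion**: rotary-encoder speed traces and run-bout detection
  (≥65 state changes in 5 s after a ≤1-change quiescent second);
* **two-photon microdomains**: most-active-minute selection, per-pixel
  binarization b = 1 iff f > median + s.d., Gaussian smoothing,
  Richardson–Lucy deconvolution (39×39 px, σ = 20 px kernel),
  percentile-band circular ROI identification (10 active + 10 inactive
  per field of view, vessels excluded below the 5th percentile) and
  pairwise Pearson correlation analysis;
* **synthetic data**: seeded generators for every input modality with
  embedded ground truth, so each pipeline is testable end to end without
  any recordings.

No raw data ship with the analyses this package reimplements, so the
generators in `fluorkit.synth` define the reference conditions and every
claim the package makes about itself is a parameter-recovery statement.

## Layout

* `src/fluorkit/` — the library: `traces`, `fitting`, `photometry`,
  `locomotion`, `linescan`, `twophoton`, `synth`, `io`, `cli`.
* `analysis/01…06_*.py` — numbered narrative drivers, one per
  experiment family; each regenerates its inputs from a seed, runs the
  pipeline and writes tables under `results/`.
* `scripts/acceptance.py` — recomputes the headline recovery numbers
  (below).

## Worked example

Dose–response and kinetics in a few lines:

```python
from fluorkit.fitting import fit_4pl
from fluorkit.synth import gen_dose_response, gen_linescan
from fluorkit.linescan import classify_membrane_pixels, fit_pixel_taus

doses, responses, truth = gen_dose_response(seed=4)   # EC50 truth 75 nM
fit = fit_4pl(doses, responses)
print(f"EC50 = {fit.ec50 * 1e9:.1f} nM, Hill = {fit.hill_slope:.2f}")

rec, truth = gen_linescan(seed=4)                     # tau truth 596 ms
cmap = classify_membrane_pixels(rec, (0.0, 1.0), (3.0, 5.0))
fits, tau_bar, gate = fit_pixel_taus(rec, cmap, ligand_onset=1.0)
print(f"gate passed: {gate}, tau-bar = {tau_bar * 1e3:.0f} ms")
```

prints

```
EC50 = 74.6 nM, Hill = 1.32
gate passed: True, tau-bar = 596 ms
```

— a single noisy titration scatters around the 75-nM truth (single-seed
estimates range widely; medians over replicates converge, see
`analysis/01`), and the line-scan trial passes the dye gate and recovers
the sub-second activation constant.

Running the drivers in order reproduces the whole study flow; e.g.

```
$ python analysis/03_photometry_stim_trials.py
median rise tau 6.88 s (truth 6.77 s); median decay tau 17.17 s
(truth 16.31 s); 0 trials excluded for poor fits
peak z rises monotonically with stimulation strength: [18.9, 100.8, 179.7, 207.5]

$ python analysis/06_twophoton_microdomains.py
sensor FOV: wake-up delta 0.27 (ramp truth 0.30), most-active minute at
154 s, 20 ROIs, 10/10 active ROIs on true hotspots, active-pair r 1.00
vs inactive 0.37
control FOV: delta 0.000 (≈0), active-pair r -0.00 (no elevation)
```

The sensor field of view shows the wake-up fluorescence ramp, exactly 20
ROIs, active ROIs on the true release hotspots and strongly elevated
active-pair correlations; the sensor-dead control shows none of these.

There is also a thin CLI (`fluorkit generate|invitro|photometry|
locomotion|linescan|twophoton`) for running single pipelines from a
shell on generated or on-disk inputs (TIFF + JSON sidecar movies, CSV
traces and hypnograms).

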