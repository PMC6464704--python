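# synaptodev

Quantification pipeline for experiments on NMDA-receptor maturation in
cortical neurons — the kind of study that tracks the developmental switch
from slow, GluN2B-dominated to fast, GluN2A-dominated NMDAR signaling and
its disruption in depalmitoylation-deficient (PPT1-knockout / CLN1-model)
neurons. It packages, as tested library code, the analyses such studies
usually run by hand in ImageJ/FIJI macros and spreadsheet formulas:

* **EPSC kinetics** — fit the decay phase of evoked NMDAR-EPSCs with a
  double exponential `Y(t) = A_f·e^(−t/τ_fast) + A_s·e^(−t/τ_slow)` and
  derive the fractional amplitudes `A_f/(A_f+A_s)`, `A_s/(A_f+A_s)`, the
  amplitude-weighted decay constant
  `τ_w = τ_fast·A_f/(A_f+A_s) + τ_slow·A_s/(A_f+A_s)`, the rise time
  (stimulus onset to peak), and per-cell percent change in τ_w under
  pharmacology (e.g. the GluN2B blocker Ro 25-6981).
* **Dendritic calcium transients** — extract a kymograph along a wide
  segmented-line ROI from a GCaMP movie, convert to ΔF/F0 with a
  per-position baseline, detect transients per synaptic site, and report
  AUC (calcium influx), diffusion distance (spatial spread above 10% of
  peak, with 65 px = 10 μm), frequency per 500 frames, synaptic synchrony
  (mean pairwise Pearson correlation of 20 site traces over 500 frames at
  7 frames/s), and before/after drug splits.
* **Puncta quantification** — fixed-threshold "analyze particles"
  semantics: 8-connected components filtered by size and circularity
  (4π·area/perimeter²; lipopigment deposits need > 8 adjacent pixels and
  circularity > 0.4, lysosomes circularity > 0.5), percent of cytosolic
  area (soma minus nucleus) occupied per cell, percent area per cortical
  column or layer in vivo, and multi-channel line scans.
* **Assay read-outs** — viability as percent of vehicle-control wells,
  band densitometry over β-actin, GluN2A/GluN2B ratios, the APEGS
  palmitoylation ratio (summed PEG-shifted bands / non-palmitoylated band,
  per actin), and t-test / ANOVA + Tukey group comparisons with s.e.m.
* **Synthetic data** — seeded generators for every input above (traces,
  movies, soma images, plate tables) with bit-reproducible ground truth,
  so the whole pipeline is testable without any raw recordings.

## Worked example

```python
import synaptodev as sd

params = sd.EPSCSimParams(amp_fast=60.0, amp_slow=60.0,
                          tau_fast=50.0, tau_slow=300.0,
                          noise_sd=3.0, seed=1)
trace, truth = sd.gen_epsc(params)
fit = sd.fit_biexp_decay(sd.normalize_to_peak(trace))
print(fit.tau_fast, fit.tau_slow, fit.frac_fast, fit.tau_w)
```

prints (see `examples/01_epsc_decay_fit.py`):

```
tau_fast  =    51.4 ms   (generated: 50)
tau_slow  =   304.3 ms   (generated: 300)
frac_fast =    0.47      (generated: 0.50)
tau_w     =   185.8 ms   (true amplitude-weighted: 175)
rise time =     8.6 ms   (stimulus onset to peak)
R^2       =  0.9777
```

The fitted time constants recover the generating fast (GluN2A-like, 50 ms)
and slow (GluN2B-like, 300 ms) components from a noisy sweep; `tau_w`
summarizes the receptor mix in a single number — a larger slow fraction
pulls it from 50 toward 300 ms. The other capabilities have matching
narrative scripts in `examples/` (calcium pipeline, puncta quantification,
viability + statistics).

A thin CLI mirrors the library for batch use:

```bash
synaptodev simulate movie --out ds/ --seed 2
synaptodev calcium-run ds/movie.tif --roi ds/roi.json --out results/
synaptodev epsc-fit traces/*.csv --stim-onset 100 --out fits.csv
synaptodev viability plate.csv --vehicle vehicle --out viability.csv
```

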