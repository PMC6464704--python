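# Methods

This note documents the models, defaults, and numerical choices behind each
pipeline stage, what the synthetic-data generators do and do not emulate,
and the known limitations. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## EPSC decay kinetics

**Model.** Evoked NMDAR-EPSCs recorded at +50 mV decay as a mixture of a
fast (GluN2A-like, ~50 ms) and a slow (GluN2B-like, ~300 ms) component.
The decay phase is fit by unconstrained least squares (`scipy.optimize.curve_fit`)
to `Y(t) = A_f·e^(−t/τ_f) + A_s·e^(−t/τ_s)` with amplitudes ≥ 0 and
τ ∈ [1, 5000] ms. There is no plateau/offset term; instead the pre-stimulus
mean is subtracted first. Components are relabeled after convergence so
that `τ_fast < τ_slow`, which makes the read-outs invariant to the
optimizer's initial labeling. The weighted decay constant is
`τ_w = τ_f·A_f/(A_f+A_s) + τ_s·A_s/(A_f+A_s)`; rise time is the interval
from stimulus onset to the peak sample (the onset reference was chosen
because the stimulus time is the one unambiguous landmark on an evoked
sweep).

**Fit window.** Defaults to [post-stimulus peak, end of sweep] — the whole
decay phase. A caller-supplied window must start at or after the peak and
contain ≥ 20 samples.

**Initialization and degenerate cases.** τ_f0 is the time for the windowed
decay to fall to 1/e of its initial value, τ_s0 = 6·τ_f0, amplitudes split
evenly. When the fitted τ ratio is < 1.2 the decay is effectively
single-exponential; the fit is still returned but flagged
(`quasi_single`), since the two-component decomposition is then not
identifiable. Sweeps are averaged pointwise (typically 5–10 aligned
sweeps) before fitting.

**Generator.** `gen_epsc` produces the biexponential decay gated at the
stimulus onset, optionally shaped by a multiplicative rise filter
`1 − e^(−t/rise_tau)` (default 2 ms; `rise_tau = 0` gives a step onset),
plus white Gaussian current noise. Default sampling is 10 kHz over a
1.5 s sweep — typical patch-clamp acquisition, and long enough to see
≈ 4.7 slow time constants of decay. Amplitude and noise defaults are
chosen for testability: recordings' absolute amplitudes are normalized
away before fitting, so only the amplitude *ratio* and the SNR matter
downstream.

**Recovery benchmark.** Parameter-recovery runs (tests and acceptance
script) generate with `rise_tau = 0`. The rise filter multiplies the decay,
so a filtered trace is not exactly a biexponential near its peak, and a
decay fit that starts at the peak inherits a small systematic bias in the
amplitude split; the pure-decay benchmark isolates the estimator's own
error. The rise filter stays in the default generator for rise-time
analysis.

## Calcium pipeline

**Kymograph.** A segmented-line ROI (default width 50 px, wide enough to
cover a dendrite plus spines) is sampled at 1-px arc-length steps; at each
step, `width_px` bilinear samples along the local perpendicular are
averaged. Bilinear interpolation is written out explicitly so that samples
landing exactly on a pixel reproduce the raster value bit-for-bit
(width-1 axis-aligned ROIs equal direct indexing). Samples outside the
image raise a geometry error rather than being clamped.

**ΔF/F0.** F0 is estimated **per position**, not as one scalar for the
ROI: per-position baselining preserves the spatial structure that the
diffusion-distance measure depends on. By default F0 at each position is
the mean of the dimmest 10% of frames there (an automatic stand-in for
manually chosen inactive frames); an explicit baseline frame set can be
supplied instead. Any non-positive F0 aborts with a baseline error.

**Sites and transients.** Candidate synaptic sites are local maxima of the
temporal-max spatial profile (threshold 0.1 ΔF/F0, greedy separation;
deterministic). Transients at a site are runs of ≥ 2 consecutive frames
(at ~7 fps, ≈ 0.3 s) in which the site-center trace exceeds 3 robust
baseline SDs (1.4826·MAD); when the baseline variance is ~0 (noiseless
synthetic data) an absolute floor of 0.05 ΔF/F0 applies. Onset/offset are
the threshold crossings; each event's spatial profile is read at its peak
frame, and a site's profile is the pointwise mean over its events.

**Read-outs.**
- *AUC* (ΔF/F0·px): trapezoidal integral of the above-baseline part of the
  site profile over the contiguous span containing the peak, including the
  bounding crossing samples (a 10-px unit plateau on a zero baseline
  integrates to 10).
- *Diffusion distance* (μm): pixel count of the contiguous run ≥ 10% of
  peak containing the peak, times the pixel size (65 px = 10 μm). The 10%
  fraction is configurable; pixel counting (no sub-pixel interpolation)
  keeps the single-pixel-spike case at exactly 1 px. A time-domain AUC is
  deliberately not the default: the distance-calibrated profile is the
  spatial-spread measure.
- *Frequency*: event count × 500 / frames analyzed.
- *Synchrony*: up to 20 sites sampled without replacement (seeded), their
  site-center traces over a 500-frame window Pearson-correlated; a site's
  synchrony is the mean of its off-diagonal correlation row. Constant
  traces are dropped with a warning (correlation undefined).
- *Before/after split*: events are assigned to the partition containing
  their **peak** frame; events spanning the boundary are flagged.

**Calibration.** 7 frames/s and 65 px = 10 μm are the package defaults
(350 frames ≡ 50 s). Both are per-dataset overridable.

**Generator.** `gen_calcium_movie` renders a horizontal dendrite band of
constant baseline fluorescence in a 2-D frame (so kymograph extraction is
genuinely exercised), with constant background autofluorescence elsewhere.
Each transient multiplies the band by `1 + a·g(x)·h(t)` with a spatial
Gaussian `g` (SD `spatial_sigma`: ~2 px emulates spine-compartmentalized
signals, ~20 px the diffuse shaft-spreading ones) and an exponential
temporal kernel (default 4 frames ≈ 0.6 s). Event onsets are per-frame
Bernoulli at `transient_rate`/500; synchrony is induced by swapping a
site's draw for a shared stream with probability `common_drive`. All three
random streams are drawn unconditionally from one seeded generator, so
movies at different `common_drive` but the same seed share one event
universe — a monotone coupling that makes synchrony comparisons across
drive levels deterministic. Default event rate (5/500 frames) and
amplitude (ΔF/F0 ≈ 1–2) match sparse spontaneous activity in the absence
of Mg²⁺. Not emulated: microscope PSF and shot noise, motion,
photobleaching, multi-neuron fields, z-structure — so passing tests
validate the measurement arithmetic and geometry, not robustness to those
real-data artifacts.

## Particle quantification

A per-channel grey-level cutoff (held identical across all images of a
comparison; no automatic thresholding) produces a binary mask; components
are 8-connected ("adjacent" includes diagonals). Circularity is
4π·area/perimeter², clamped to ≤ 1 for rasterization overshoot. The
perimeter is the Crofton-formula estimate (4 directions,
`skimage.measure.perimeter_crofton`): it converges to the true boundary
length for finely rasterized shapes and stays honest for 1-px-wide
structures, so a 30-px line scores ≈ 0.11 (rejected by the lipopigment
filter) while a radius-10 disc scores ≈ 0.94. Simpler pixel-crossing
estimators fail one or the other regime. Presets: lipopigment deposits
need > 8 adjacent pixels (≥ 9, read strictly from "more than eight") and
circularity > 0.4; lysosomes need circularity > 0.5. Per cell, cytosolic
area is the soma mask minus the nucleus mask (within the soma ROI, which
defaults to the soma threshold mask when no polygon is given), and percent
area is particle area over cytosolic area. In vivo, percent area uses the
full image (or rectangular layer ROIs) as denominator — a tissue mask is
not attempted. The soma-image generator rasterizes discs (lysosomes) and
sinusoidally-perturbed discs (lipopigment, tunable irregularity), placing
them without overlap inside the cytosolic ring with bounded retries; its
truth records each particle's pixel count and circularity computed
directly on the particle's own mask, independent of the analysis path.

## Assays and statistics

Viability: each well over the same-plate vehicle mean × 100 (vehicle mean
is exactly 100% by construction); cross-plate pooling happens after
normalization. Densitometry: band/actin within lane; the GluN2A/GluN2B
ratio cancels actin but accepts it for the audit trail. APEGS: palm = sum
of PEG-shifted band densities, ratio = (palm/nonpalm)/actin, with the
non-palmitoylated band identified as the one matching the −HA control
lane; the ratio is invariant to how a shifted pool is split across bands.
Group comparisons: Student's t (Welch optional, off by default to match
plain-t reporting conventions), one-way ANOVA + Tukey HSD, and two-factor
ANOVA (type II, with interaction) + Tukey on the factor cells, via
scipy/statsmodels. s.e.m. = sd/√n with n = independent experiments;
`average_technical_replicates` pre-averages technical repetitions so they
never inflate n. Two-way designs average repetitions out rather than
modeling them as a factor.

## Problem sizes and tolerances

The test and acceptance workloads are sized to be quick while keeping
estimates stable: 100 EPSC traces at SNR 20 for recovery medians; calcium
movies of 600 frames × 24 × 650 px with 5 sites (500 frames × 10 sites for
synchrony); 50 random 64×64 masks for labeling equivalence; 1000 null
simulations for the type-I rate. Fixed comparisons use exact or
closed-form oracles (weighted-τ arithmetic to 1e−9, Gaussian integral to
1%, FWHM on a σ = 50 px Gaussian to 2% — σ chosen so pixel quantization is
negligible, raster equality exact).

## Known limitations

- The biexponential decomposition is ill-conditioned when the two time
  constants approach each other; the quasi-single flag marks, but does not
  resolve, that regime.
- Transient detection is a threshold rule, not deconvolution; closely
  spaced events within one threshold crossing merge into one detected
  event, which biases frequency slightly downward at high rates.
- Diffusion distance is quantized to whole pixels; at very narrow spreads
  (≲ 5 px) the quantization error is a substantial fraction of the value.
- Circularity of small (< ~20 px) particles is a coarse shape descriptor;
  the presets follow the stated rules rather than attempting scale
  correction.
- Layer ROIs are axis-aligned rectangles; anatomical layer delineation is
  out of scope, as are cell segmentation, motion/bleach correction and
  gel-image densitometry (band densities are consumed as numbers).
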