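# Methods

## Problem setting

A correlative fluorescence–Raman experiment images the same single cells
twice: a fluorescence microscope (DAPI-stained nuclei) is used to find and
annotate cells, and a Raman microscope then records a spectral map of each
cell — a 24×24 pixel grid at 1 µm step where every pixel holds a
1600-channel spectrum over 439–3228 cm⁻¹. The analysis task is to assign
each cell to interphase or one of the five mitotic stages (prophase,
prometaphase, metaphase, anaphase, telophase) from its spectral map alone.
This package implements the full computational side of that experiment:
robust spectral normalization, cross-microscope registration, band-interval
imaging, and the stage classifier, plus a simulator that stands in for the
(non-public) measured data.

## Reference fitting (the normalization model)

Raw cell spectra are corrupted by two dominant distortions: a
multiplicative intensity fluctuation from laser-power drift, and a smooth
additive baseline, largely fluorescence. Both are removed at once by
fitting every spectrum `S` to a single reference spectrum `R` through

    Ŝ(a, P) = a·S + P,     P_j = p(x_j),    p(x) = Σ_{i=0..n} p_i x^i

minimizing `½ Σ_j L_δ(Ŝ_j − R_j)` over the scale `a` and the n+1
polynomial coefficients, where `L_δ` is the Huber loss (quadratic within
δ of zero, linear beyond). The linear tail means large residuals — the
sharp Raman peaks that carry the chemical signal and must *not* be matched
to the background reference — contribute a bounded gradient, so only the
baseline and overall intensity are pulled toward the reference.

Choices and defaults:

- **n = 5** (quintic baseline), **δ = 0.02**. δ is meaningful because both
  spectra are SNV-transformed (per-spectrum mean 0, sample sd 1, `n−1`
  denominator) before fitting (`snv_first=True`); δ is then a fixed
  fraction of one reference standard deviation, independent of detector
  counts. SNV is read as a persistent preprocessing step: fitted spectra
  are returned in the space in which the fit ran, and `FitResult.space`
  records which space that was. Setting `snv_first=False` fits in raw
  units.
- The polynomial is evaluated on the channel coordinate mapped affinely to
  [−1, 1]. Raw channel indices 0..1599 raised to the fifth power make the
  system catastrophically ill-conditioned; the centered coordinate keeps
  the design matrix benign. Coefficients are reported in that frame.
- The sum runs over all m = 1600 channels.
- **Optimizer**: the objective is smooth and 7-dimensional, so a
  deterministic quasi-Newton method (L-BFGS-B) with the analytic gradient
  is used, started at `a = 1, p = 0`. Convergence tolerance is tight
  (`tol = 1e-13` on the relative objective change) so that results are
  reproducible to ~1e-6 relative across equivalent inputs (e.g. rescaled
  spectra). The returned objective never exceeds the start-point value; if
  the optimizer fails, the start point is returned with
  `converged=False`, never silently.
- `a` is unconstrained; a non-positive fitted scale is logged as a
  warning. The reference is an explicit argument; `average_background`
  (channel-wise mean over user-masked background pixels) is the
  recommended way to construct it.
- A `loss="squared"` variant exists solely for comparison runs; it is the
  same optimizer with `L(x) = x²` and demonstrates why the robust loss is
  needed (peaks drag a squared-loss fit off the baseline).

Standard SNV and iterative polynomial baseline subtraction (modified
polyfit: fit, clip the spectrum to the fit, repeat until the baseline
changes by less than `tol`) are provided as the conventional alternatives
the reference fit is compared against.

## Cosmic-ray despiking

Cosmic rays hit single detector channels at single pixels. The detector
computes, per channel, a robust z-score against a short spectral window
(default 5 channels) centered on — but excluding — the channel:
`z = (x − median) / scale`. The scale is the windowed MAD calibrated for
its finite sample size: with only 4 neighbors the raw MAD underestimates
σ badly (E[MAD₄] ≈ 0.496 σ rather than the asymptotic 0.6745 σ) and the
window median contributes extra residual variance (×1.14 for 4
neighbors), so both corrections are folded in, using constants tabulated
from the Gaussian distribution. The scale is additionally floored at the
per-spectrum median of the windowed scales, because a 4-sample MAD is
occasionally near zero even on pure noise, which would explode the
z-score. Without the calibration and floor, the detector produced
hundreds of false positives per map; with them, none on the default
simulator conditions.

A channel is flagged when `z > z_thresh` (default 8) **and** the same
channel at every 4-connected spatial neighbor stays below `z_thresh / 2`:
genuine Raman peaks are spatially coherent across neighboring pixels of a
cell, cosmic rays are single-pixel events. Flagged channels are replaced
by linear interpolation from the nearest unflagged channels (constant
extrapolation at spectrum ends). The same floored, calibrated scale
defines the "local MAD unit" in which the simulator expresses injected
spike amplitudes, so detector and simulator speak the same units.

## Registration

Cell positions selected under the fluorescence microscope are carried to
Raman-stage coordinates by a projective transformation (homography)
estimated from ≥ 4 engraved registration marks per well. Estimation is
the normalized direct linear transform: both point sets are translated to
their centroid and scaled to mean distance √2, the 2n×9 homogeneous
system is solved by the smallest right singular vector, and the result is
denormalized and scaled to `H₃₃ = 1`. Four non-degenerate pairs give an
exact fit (residual < 1e-9 µm); more give the algebraic least-squares
homography. No outlier rejection is performed — with four engraved marks
per well there is nothing to reject — but `registration_rmse` reports the
residual for quality control. Degenerate configurations (three collinear
source points among four) raise an error naming the offending points.

## Band images

A band image reduces a map over a closed wavenumber interval (channel
membership by the axis, both endpoints included, no interpolation),
default reducer `mean`. The two diagnostic intervals are 775–795 cm⁻¹
(pyrimidine ring breathing; DNA, hence chromatin) and 2820–3020 cm⁻¹
(CH₂/CH₃ stretches; mostly lipids and proteins). `region_contrast`
quantifies nucleus/background separation as Cohen's d with pooled n−1
variances; on simulated cells this contrast is higher after reference
fitting than on the raw distorted map, which is the package's quantitative
version of the qualitative preprocessing comparison.

## Stage classifier

Spectral maps are images with 1600 channels, so the network splits into a
channel section and a spatial section:

1. grouped 1×1 convolutions reduce 1600 → 400 → 100 → 32 channels (group
   counts 8, 4, 4) — per-pixel channel mixing that learns which
   wavenumber ranges matter while keeping the weight count manageable;
2. plain 3×3 convolutions (32 → 64 → 64, zero-padded, stride 1) mix
   spatially;
3. global average pooling, then exactly two fully connected layers
   (64 → 128 → 6) produce the class scores.

All widths, group counts, and depths are configuration fields; the
defaults above are this package's own choices of plausible sizes for the
published layer structure. ReLU activations, He-normal initialization
deterministic under the config seed. The implementation is a small
hand-written numpy engine (forward, backward, Adam) — about 155k
parameters, comfortably trainable on one CPU.

Training feeds 15×15 crops whose offsets lie on a 2-pixel stride grid
(25 crops of a 24×24 map), a cheap augmentation that also caps memory.
Crops inherit their parent cell's label. Augmentation applies to training
cells only; validation and test cells are evaluated intact: every crop of
the cell is scored and the logits averaged (`mean_logits`; a majority
vote with mean-logit tie-break is available), so all reported accuracies
are per cell. Splitting is by cell (70/15/15, stratified by stage,
largest-remainder apportionment, ties toward the earlier partition) so no
crop of one cell can appear in two partitions. Inputs are per-pixel
SNV-standardized spectra, which removes the multiplicative drift and mean
offset at the network input. Training uses cross-entropy and Adam
(lr 1e-3, batch 32); per epoch each training cell contributes a sampled
subset of its crop grid (default in the pipeline: 10 of 25), which
decorrelates batches and keeps an epoch cheap. Everything is
deterministic under a fixed seed and thread count.

Because the six stages are temporally ordered (interphase adjacent only
to prophase), a prediction on a neighboring stage is a near miss. The
one-miss accuracy is the tridiagonal mass of the 6×6 confusion matrix
(|row − col| ≤ 1) over its total; it can never be below the standard
accuracy (trace over total).

## Simulator

Each simulated pixel spectrum is

    a_px · [reference + w_ch(px)·cyto_bands + w_dna(px)·dna_peak]
        + baseline_px + ε

— exactly the distortion family the reference fit is designed to undo,
with `a_px ~ U(0.7, 1.4)`, a per-pixel random quintic baseline with
coefficients in [−0.3, 0.3] (in the [−1, 1] channel coordinate), and
i.i.d. Gaussian noise (sd 0.01, about 1% of the reference range;
intensities are arbitrary units with the reference of order 1). The
reference background is a gentle polynomial plus 2–4 broad Gaussians
(widths ≥ 300 cm⁻¹) plus 3–5 medium-width features (80–150 cm⁻¹). The
medium features are essential to a well-posed simulation: if the
reference were representable by the quintic baseline term alone, the
robust fit could mimic it without using the spectrum at all (a → 0), and
for peak-heavy pixels it would prefer to — the linear Huber tail prices
peaks proportionally to `a`. Real backgrounds carry such structure; so
must the simulated one. For the same reason the spectral bands are kept
baseline-dominated, as in fluorescence-contaminated cell spectra: the DNA
band is a Gaussian at 785 cm⁻¹ (σ = 10 cm⁻¹, strength 1.2) and the
cytoplasm template a four-Gaussian CH₂/CH₃ mixture in 2820–3020 cm⁻¹ plus
the 1003 cm⁻¹ phenylalanine peak, both scaled well below the
quintic-unrepresentable mass of the reference. Spatial weights are
smoothed stage masks, strictly zero outside them. Cosmic rays are
injected as Poisson(10) single-channel spikes per map at 20 local-MAD
units.

Stage geometries are coarse archetypes ordered along the mitotic
continuum: diffuse interphase ellipse; smaller dense prophase blob;
prometaphase blob with a partial bar (deliberately intermediate between
prophase and metaphase); metaphase plate (elongated bar, aspect ≥ 2);
anaphase twin masses at distance d₁ ≈ 6.4 px; telophase twin masses at
d₂ ≈ 10.4 px with pinched, dumbbell cytoplasm. Position and orientation
are randomized per cell.

What the simulator does **not** model: Poisson shot noise (Gaussian noise
keeps recovery tests interpretable; a real detector is
shot-noise-limited), physically calibrated Raman cross-sections, peak
overlap and the crowded fingerprint region, fluorescence bleed-through,
sample drying/bending distortions, or realistic chromatin texture.
Passing tests therefore demonstrate that the algorithms are correct and
that the pipeline can extract stage-ordered spatial-spectral structure —
not that the classifier's accuracy on these archetypes transfers to
measured cells.

## Problem sizes and numerical notes

- The end-to-end learning check trains on 6×30 simulated cells (126
  train / 30 validation / 24 test after the stratified split), 12 epochs,
  10 crops per cell per epoch — a scale chosen so the whole suite runs
  comfortably on a laptop-class single core while still leaving the
  chance-level null rejected at p < 0.01 by an exact binomial test.
- Despiking efficiency is measured pooled over 20 default-condition maps
  (~200 spikes).
- `nearest_channel` breaks distance ties toward the lower index;
  `split_cells` breaks apportionment ties toward the earlier partition;
  majority-vote ties fall back to mean logits. All three rules exist so
  that behavior is exactly reproducible.
- Degenerate inputs fail loudly: constant spectra (SNV), fully flagged
  spectra (despike replacement), empty masks, zero pooled variance,
  collinear registration points, and maps smaller than the crop all raise
  typed errors.
- The pipeline report's checksum is computed over the deterministic
  content only (timings are excluded), so identical configs and seeds
  give identical checksums.

## Known limitations

- The Huber fit assumes the reference and the spectrum differ by scale
  plus a degree-n polynomial; chemically different backgrounds violate
  this and show up as non-converged pixels or large losses (both are
  reported, never dropped).
- The despiking veto assumes spikes are spatially isolated; two cosmic
  rays hitting the same channel of adjacent pixels would veto each other.
  At realistic spike rates this is vanishingly rare.
- Accuracy numbers obtained on the simulator say nothing quantitative
  about measured cells; the published headline accuracies on the private
  dataset are explicitly out of scope.
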