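# Methods

This note records the models behind `sdstorm`, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the
numerical and design choices made where more than one reasonable option
existed.

## Strand-displacement gates

A gate is a protector/template/invader triple. All sequence arithmetic uses
strict Watson–Crick pairing (A·T, G·C, no wobble) on upper-cased DNA; RNA
(U) is rejected. The printed protectors carry a 3′ `TT` spacer before the
azide used for antibody conjugation; it is modeled as a non-hybridizing
*linker* field excluded from every complementarity computation, which
reconciles the 32 synthesized characters with the 30-nt hybridizing region
and the 30-bp duplex.

**Duplex mapping.** The maximal ungapped antiparallel alignment is found by
scanning all diagonals `i + j = const` of the pair matrix
(`a[i]` pairs `b[j]` iff `a[i] = complement(b[j])`) and keeping the diagonal
with the most pairs. Ties are broken by the smallest absolute offset between
`a` and `reverse_complement(b)`, then by the 5′-most start on `a` —
an arbitrary but deterministic rule. The toehold is the contiguous template
region the protector leaves unpaired; a non-contiguous unpaired region is an
error (such a "gate" is not a toehold gate), and a fully paired template
raises a zero-length-toehold error since displacement could not nucleate.

**Orthogonality.** Cross-reactivity between sets is scored as the longest
ungapped antiparallel complementary run over all 9 inter-set strand pairs,
checked exactly against a brute-force all-substrings oracle in the tests.
The default classification threshold (max run < 10 consecutive pairs) is a
package convention — a sequence-level stand-in for a thermodynamic criterion
— and is always reported with the result, never applied silently. Runs of
~10 bp correspond to duplexes marginal at room temperature, so the default
is conservative for the 4-bp worst case of the built-in sets.
Nearest-neighbor free-energy or ensemble secondary-structure prediction is
out of scope.

## Displacement kinetics

The invader is micromolar while bound template is a surface species, so
displacement is pseudo-first-order with effective rate `k_eff = k_disp · c`
and treated as irreversible (the toehold bases the invader gains bias the
reaction to completion). The observable intensity is

```
I(t) = A · e^{−β t} ·  { 1                                  t < t0
                       { 1 − (1 − f_res)(1 − e^{−k_eff (t − t0)})   t ≥ t0
```

with bleaching rate `β` (s⁻¹), invader-addition time `t0`, and a residual
fraction `f_res` of never-displaced template. Defaults: `k_disp = 10⁵
M⁻¹s⁻¹`, on the published scale for long (≥ 6 nt) toeholds — any value above
~2×10³ M⁻¹s⁻¹ saturates in under 5 minutes at 4.87 µM — and `c = 4.87 µM`,
the experimental invader concentration. Both are configurable; the model
depends only on their product.

**Fitting.** `β` is estimated by log-linear regression on the pre-invader
segment (the ~20 s imaged before invader addition exists precisely to
establish the bleaching rate) and held fixed; amplitude, `k_eff`, and
`f_res` are then fitted to the full normalized trace by bounded least
squares (`scipy.optimize.least_squares`, tolerances 1e-15 so noiseless
round trips recover parameters to ≲1e-6). Initialization: `k_eff` from the
first time the bleach-corrected post-segment falls to 1/e of its
displaceable span, `f_res` from the mean of the final 10% of samples. At
least 10 samples are required on each side of `t0`. Percent reduction is
reported both bleach-corrected (`100·(1 − f_res)`, the model plateau) and
raw (from the normalized data as observed), since whether measured traces
were bleach-corrected before normalization is ambiguous in practice.
Non-convergence is flagged on the result object, not raised.

## Synthetic acquisitions

The generator produces the study conditions for every closed-loop test.

**Scenes.** Filaments are line segments with binding sites at exact linear
spacing (default 20 nm, microtubule-antibody scale); clusters are disks of
75 nm radius with Poisson site counts (clathrin-pit scale). Geometry is
schematic: real tubulin curvature, pit maturation stages, and labeling
stochasticity beyond Bernoulli thinning are not modeled, so passing tests
demonstrate the *analysis chain*, not biological realism.

**Labeling and carryover.** Each round labels its target's sites
Bernoulli(`label_prob`, default 0.9); a fraction `carryover_residual` of the
*previous* round's labeled sites remains dye-bound, modeling incomplete
invader displacement. This is the ground truth against which measured
cross-talk is judged.

**Photophysics.** Dark fluorophores activate with probability `p_on` per
frame, stay on a geometric number of frames (mean `mean_on_frames`), emit
`photons_per_frame` expected photons per on-frame, and may bleach per
on-frame. Defaults (`p_on = 8×10⁻⁴`, mean on 2 frames, 800 photons/frame)
give dSTORM-like sparsity (~5 active emitters per 64×64 frame) and photon
counts typical of AF647 at 60 Hz. Partial on-frames at switching boundaries
are not modeled; an emitter is fully on or off within a frame.

**Image formation.** Expected pixel value `μ_k = N·Ex_k·Ey_k + b`, with
`Ex`, `Ey` the per-axis integrals of a Gaussian over the pixel (erf
differences), PSF width default σ = 1.3 px ≈ 139 nm — typical for a
1.45-NA objective at ~685 nm — and uniform background `b` (default 5
photons/px). Frames are independent Poisson samples; the default output is
photon units so the localizer's Poisson likelihood matches the generator
exactly. An optional EMCCD stage applies gamma-distributed gain
(shape = photon count, scale = EM gain), ADU conversion
(`adu_per_electron`, counts per gain-register electron), offset, and
Gaussian read noise; its back-conversion divides by
`adu_per_electron · em_gain` and can optionally halve effective counts to
approximate excess noise — an approximation that is documented and off by
default. Coordinates: x right / y down, origin at the center of pixel
(0,0), sub-pixel position 3.0 = center of pixel 3.

**Time-course movies.** In the low-excitation regime used for displacement
traces (2 Hz), all dye-bound sites emit continuously; the expected per-site
emission scales with the kinetics intensity model (mean-field — individual
sites are not assigned discrete displacement times) and each frame is
Poisson-sampled.

**Scale.** Desk-scale defaults are 64 × 64 px and 2,000 frames per round
(the published acquisitions are 256 × 256 and 20 × 2,000 frames per target);
full scale is a config change, not a code change.

## Localization

**Detection.** Difference-of-Gaussians band-pass (σ and 2σ), local maxima
above a photon threshold (default 5, calibrated so that a 250-photon emitter
at σ = 1.3 px produces a DoG response ≈ 7 photons while smoothed background
noise at b ≤ 10 stays well below), merging maxima closer than half an ROI
(brighter wins; ties to smaller row, then column), border-clipped ROIs
discarded. Two emitters ≲ 2 px apart merge to one candidate — a documented
single-emitter limitation.

**MLE.** Parameters (x, y, N, b) are refined by 20 sequential per-parameter
Newton–Raphson updates `θ ← θ − (∂LL/∂θ)/(∂²LL/∂θ²)` on the Poisson
log-likelihood, positions initialized at the background-subtracted center of
mass, N at (sum − roi²·min), b at the ROI minimum. Steps are capped (1 px
for positions, 5 for b, max(100, N/2) for N) and N, b clamped positive; no
line search, matching common practice for this fitter class. σ is fixed
during the fit (the 4-parameter form); a 5-parameter variant fitting σ is
available but off by default. Fits whose center leaves the ROI are flagged
`diverged`; a non-invertible Fisher matrix flags `singular_fisher`.

**Precision and goodness of fit.** CRLBs come from inverting the 4×4 (or
5×5) Fisher information of the pixel model. The data-model test is the
Poisson deviance `2 Σ_k [μ_k − d_k + d_k ln(d_k/μ_k)]` referred to
χ²(roi² − n_params). This reference is asymptotic in per-pixel counts: at
background ≥ ~10 photons/px the rejection fraction at p < 0.01 is
1.0–1.4%, while at background 2 it inflates to ~2% (Monte-Carlo,
5,000–20,000 ROIs). The calibration test therefore runs at background 10;
at the simulator's default background 5 the filter discards a slightly
conservative extra ~1% of correct fits, identically before and after
invader treatment, so ratio measurements are unaffected.

**Filtering.** Accepted iff background ≤ 200 photons AND photons ≥ 250 AND
p ≥ 0.01. The thresholds are stated values; inclusivity at the boundary is
a package choice (inclusive for acceptance) and is pinned by a dedicated
boundary test. Filtering preserves order, never mutates fitted values, and
records per-row rejection reasons.

## Quantification

**Rendering.** Each accepted localization adds a unit-integral anisotropic
Gaussian with σ = (CRLB_x, CRLB_y), truncated at 5σ and discretely
normalized, at zoom 10 SR px per camera px (both conventions, not measured
values). Image mass therefore equals the rendered count; localizations with
CRLB > 1 camera px are rendered but counted in a flag, never silently
dropped.

**Traces.** A scalar per-frame background offset is estimated as the 20th
percentile (configurable) of a Gaussian-smoothed copy of the frame — the
smoothing (default σ = 5 px) removes the shot-noise bias a percentile of
raw Poisson pixels would carry — and subtracted from the frame sum, which
is clamped at zero; the trace is normalized to its maximum. Per-pixel
zero-clamping is deliberately avoided: rectifying Poisson noise adds a
positive floor of order `E[max(P(b) − b, 0)]·n_pixels` that would swamp a
few-percent residual level.

**Cross-talk.** The after/before ratio of accepted localization counts from
equal-length acquisitions under identical filters. Equal lengths are
*required* (counts scale with frames). The closed-loop tolerance used in
the acceptance test is three standard errors of the ratio estimator under
the generative model, which has two Bernoulli layers: the carryover draw
over the `n` labeled sites, variance `r(1−r)/n`, and the photoswitching
activations of the carried emitters — activations per site ≈
Poisson(λ = p_on·n_frames) with geometric on-times of mean `m`, adding
`r·(2m−1)/(λm)/n`. At r = 5%, 2,000 frames, and ~1,100 sites the two terms
are comparable (combined SE ≈ 0.009), matching the empirical spread of
repeated simulations.

**Registration.** Normalized FFT cross-correlation over all integer shifts
with parabolic sub-pixel refinement of the peak, on a target-independent
pseudo-brightfield reference image (all binding sites smoothed to σ = 2 px)
— the computational replacement for brightfield-based stage re-alignment
between rounds. Different rounds image different structures, so registering
their fluorescence directly would be meaningless; the pseudo-brightfield
plays the role of the cell's label-independent outline. Flat (zero-variance)
images raise a registration error.

## Experiment orchestration

One YAML config describes scene, camera, photophysics, rounds, filters, and
kinetics; validation reports every violation with its key path and
normalizes units ("4.87 uM" → 4.87×10⁻⁶ M, "5 min" → 300 s, "106.7 nm" →
0.1067 µm). Per-round seeds derive deterministically from the experiment
seed via `numpy.random.SeedSequence`, so any report is bit-for-bit
reproducible from its echoed config. Between consecutive rounds an
equal-length post-invader acquisition (fresh labeling off, only the
carryover fraction bound) is simulated and localized to measure cross-talk
exactly as the before/after comparison is done on real cells. Wet-lab
exchange steps (washes, incubation timing) are represented only through the
round specifications and the kinetics module.

## Known limitations

- Single-emitter fitting only: overlapping emitters merge at detection and
  bias dense scenes; the default activation rate keeps scenes sparse.
- The deviance/χ² test is anti-conservative at very low backgrounds (see
  above).
- The EMCCD excess-noise treatment is a documented approximation; the exact
  likelihood for gamma-amplified Poisson data is not implemented.
- Structure geometry is schematic; absolute localization counts are not
  comparable to real cells, only ratios and stability measures are.
- No drift within a round, no 3D, no multi-emitter or sCMOS noise models.
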