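# Methods

This note documents the model and the numerical choices behind
`flfaquant`: what the pipeline computes, why its defaults are what they
are, what the synthetic data generator does and does not emulate, and the
known limitations.

## Signal model and pipeline

A strip image is an h × w gray matrix `f(x, y)` (row y, column x; column
index runs along the strip's long axis, crossing the capture lines). The
physical scene is assumed to be a smooth elevated background (stray light
reaching an unfiltered sensor), plus non-negative fluorescent bands with
smooth unimodal cross-sections, plus sensor noise. The pipeline:

1. **Projection.** `Y_j = Σ_i y_ij` collapses the image (or a
   sub-rectangle) along one axis. Sums, not means: downstream validity
   thresholds are positional, so overall scale is irrelevant, and integer
   arithmetic stays exact.

2. **Transform.** The projection curve is convolved with sampled Mexican
   Hat wavelets `ψ(t) = (1 − t²/σ²) exp(−t²/2σ²)` at scales σ = s for
   s = 30…37, each normalized by 1/√s, and the eight coefficient curves
   are averaged point-wise into the detection curve W. The Mexican Hat's
   single positive lobe cannot create positive interference peaks, and
   averaging nearby scales stabilizes the response without washing out
   localization (`aggregate` also offers `max` and `single_scale`).

3. **Peak seeking.** The interval derivative
   `W'_j = (W_{j+n} − W_{j−n})/(2n+1)` (half-width n = 2 by default;
   the 2n+1 denominator is kept as such — zero-crossing positions are
   denominator-invariant, which is all that matters downstream) yields
   apexes at +→− sign changes and troughs at −→+ changes; curve ends are
   fallback troughs. A peak is *valid* when its trough separation
   exceeds μ = 32 samples, and *accepted* when it additionally clears
   the SNR rule below.

4. **Positioning.** X projection → accepted peaks → column slabs; inside
   each slab, Y projection → no accepted peak means a uniform strip band
   (full-height ROI), otherwise one spot ROI per Y peak (dot-matrix
   format). A `mode` hint can force strip handling.

5. **Quantification.** Every ROI row is pushed through the same
   transform + peak machinery (support and scales shrink automatically to
   the row length). Rows with an accepted peak contribute the
   background-subtracted area between their trough columns and that
   width; `avePix` is total area over total width. Rows with no accepted
   peak contribute neither — at low contrast, folding undetected rows in
   at region-wide bounds would dilute exactly the weak signals the method
   exists to preserve. Trough *positions* always come from the
   transformed curve; baseline *values* are read from the raw curve being
   quantified (projection curve at positioning stage, raw image row at
   quantification stage). The reported relative fluorescence intensity is
   avePix / full-scale gray.

## Numerical choices

**Kernel truncation and the zero mean.** The default support of 128
samples cuts the scale-30…37 kernels at under 2σ, where the sampled
Mexican Hat no longer sums to zero (Σψ ≈ 19.5 at σ = 33 against a peak
of 1). The transform therefore subtracts each kernel's support mean
before convolving, restoring the vanishing moment exactly: constant
backgrounds are annihilated to machine precision, and by symmetry linear
stray-light gradients as well. `mexican_hat_kernel` itself returns the
pure analytic samples, so ψ(0) = 1 and ψ(±σ) = 0 hold exactly. Even
support lengths are widened by one sample to keep the kernel symmetric
about zero.

**Boundary extension.** Each curve end is continued by a straight line
fitted to the adjacent kernel-length of samples. The alternatives fail
concretely: even reflection folds a background gradient into a crease
whose response can exceed a weak band's by two orders of magnitude, and
any reflection mirrors the *noise*, inflating detection-curve variance
near the ends — measured on blank noisy scenes, roughly a third acquired
a spurious accepted edge peak under odd reflection. The fitted line
continues the trend with essentially no noise. Both reflections remain
selectable (`reflect_odd`, `reflect_even`).

**Peak SNR.** Because the transform has an exact zero baseline, apex
height above zero is the natural signal estimate; the noise level of the
detection curve is the input noise σ̂ (median absolute successive
difference of the raw curve, robust to bands, gradients and sparse
impulses) times the L2 norm of the aggregated kernel. The default
threshold `min_snr = 10` was calibrated by simulation on blank noisy
scenes: the largest noise-peak SNR observed across 600 scenes was ~6.5,
while the weakest band the generator produces (contrast 2σ over a
200-row projection) carries SNR above 150 — the threshold sits an order
of magnitude below signal and safely above noise. Scoring SNR from the
troughs instead would admit the rebound bumps flanking a real peak's
negative side lobes, whose trough-relative prominence scales with the
band itself; their apexes, by contrast, never rise above zero. A
`min_prominence` criterion (disabled by default) is available on top.

**Edge margin.** Apexes closer to a curve end than
min(kernel half-width, length/4) are rejected: there the kernel hangs
substantially over synthesized samples, and a band located just inside
the boundary-fit window can manufacture ghost peaks at the frame edge.
Capture lines sit well inside the imaged window, so the margin costs
nothing; for scan lines the rule keeps the central half of the region,
where the band apex lies by construction.

**Short curves.** Profiles shorter than the kernel support (ROI scan
lines) shrink the support to the profile length and drop scales that no
longer fit the half-support, falling back to the half-support itself if
none fit. Curves under 9 samples are refused.

**Degenerate flat input.** A noise-free constant curve transforms to
numerical ripple (~1e−13); an absolute floor of 1e−9 × the reference
curve's magnitude prevents such ripple from ever being scored as a peak.

## Parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| scales | 30…37 | kernel σ in samples; matched to capture-line half-widths of ~20–26 px (response is maximal near s ≈ √2 σ_band) |
| support_len | 128 | kernel support in samples |
| aggregate | mean | combination rule across scales |
| boundary | extrapolate | curve extension at the ends |
| n | 2 | derivative half-width; smooths single-sample jitter |
| μ (mu) | 32 | minimum trough separation of a valid peak (samples) |
| min_snr | 10 | minimum apex SNR (see calibration above) |
| min_prominence | 0 | optional absolute prominence gate (detection-curve units) |
| channel_policy | red | quantum-dot emission is red; `luminance` offered for generality |

4PL fitting starts from A and D at the responses of the lowest/highest
dose, C at the dose nearest the half-range signal, B = 1 (the A/D
orientation encodes response direction, covering sandwich and competitive
assays), and solves unweighted least squares (optional per-point or 1/y²
weighting). The parameterization is degenerate under
(A, D, B) → (D, A, −B); fits are reported with C > 0.

## Synthetic scenes and ground truth

The generator emulates the filter-free regime: an elevated background
(base ~30–60 gray on 8-bit) with linear/quadratic stray-light gradients,
Gaussian band cross-sections (σ_band ~18–26 px, spanning the full strip
height, as capture lines cross the imaged window) or isotropic Gaussian
spots, additive Gaussian read noise (σ = 2 gray by default), optional
saturated salt impulses, then clipping and quantization to 8 or 16 bits.
Flat-topped bands (box ⊗ Gaussian) are available for robustness checks.
Everything is reproducible from the scene seed, and pre-quantization
scenes superpose exactly.

The weak-signal suite draws 50 scene geometries (1–3 bands, integer
centers ≥150 px apart and ≥90 px from the frame edge, shared width and
background per scene) with band amplitudes uniform in 2–4× the noise σ,
and renders 5 noise replicates per geometry. The noise-robustness
variant uses ~6× σ contrast, doubles the noise to σ = 4 and adds 0.5%
salt pixels. These are the conditions under which the accuracy figures
in `scripts/acceptance.py` are computed (problem size: 250 images of
200 × 600 px per suite), scored by strict localization: every true band
matched within 5 px by an accepted peak and no unmatched accepted peak.

Ground truth carries closed-form expectations from `flfaquant.analytic`:
the noise-free detection response of a Gaussian band under the truncated,
mean-corrected kernels is an erf/exp expression (the Mexican Hat has the
exact antiderivative t·exp(−t²/2σ²); Gaussian × Mexican-Hat integrals
reduce to truncated-normal moments), the detector's trough offset T is
its stationary point, and the analytic avePix follows from the Gaussian
integral over ±T minus the window baseline. The scan-line regime is
modeled separately (finite profile window, shrunken kernel, constant
continuation at the fitted level); the prediction reproduces the
pipeline's row windows to ~1 px and its avePix to within ~2% on
noise-free bands. The spot formula additionally excludes rows whose
amplitude rounds to zero at the bit depth and is accurate to a few
percent. These formulas never call the wavelet or peak code.

**What the generator does not emulate** — and what passing tests
therefore do not establish about real data: optical point-spread
functions, non-Gaussian or asymmetric band profiles, membrane texture
and flow artifacts, strip rotation or skew (the reader's strip chamber
fixes alignment), Poisson shot noise, color-filter-array demosaicing,
and illumination flicker. Real backgrounds are smooth but not exactly
polynomial; the pipeline only requires them to be smooth at the scale of
the kernel. One degenerate synthetic regime is worth naming: a
noise-free scene whose background varies along exactly one axis can
alias into projection staircases after integer quantization; any
realistic noise (σ ≥ ~0.5 gray) dithers this away.

## Limitations

* Bands closer than roughly twice the trough offset (~120 px at default
  scales) merge into one detection; the suites enforce 150 px spacing,
  matching physical T/C line separation.
* Apexes within the edge margin of the frame are not reported; capture
  lines at the very frame edge are out of scope.
* avePix on signals near the quantization limit (peak amplitude of a few
  gray levels) carries rounding bias of up to ~10–15% even noise-free;
  localization is unaffected.
* The μ rule as printed tests total trough separation; an alternative
  reading (asymmetry between half-widths) was considered and not
  adopted.
* At the default scales an isolated impulse's transform response is
  kernel-wide, so impulse rejection in the full pipeline rests on the
  SNR rule, not on μ; the μ rule still rejects narrow structures on
  curves analyzed at small scales.
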