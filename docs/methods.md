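# Methods

## Model

The package implements texture enhancement of 8-bit single-channel images
by fractional-order differential convolution masks. Fractional
differentiation of order α ∈ (0, 1] interpolates between the identity
operator (α → 0⁺) and the classical first difference (α = 1); applied to
an image, intermediate orders pass mid-frequency texture while attenuating
neither smooth regions (as a first derivative would) nor noise as strongly
as integer-order sharpening.

Two fractional-calculus objects underlie the masks:

* the Grünwald–Letnikov (GL) series with signed generalized-binomial
  weights (−1)ᵏ·C(α, k), evaluated by the stable recurrence
  `w[k] = w[k−1] · (k−1−α)/k`, `w[0] = 1` (the direct Γ-ratio formula is
  kept as a test oracle only, since it overflows for large k);
* the Atangana–Baleanu operator with the Mittag-Leffler kernel
  E_n(t) = Σ tᵏ/Γ(nk+1) and normalization M(α) = 1 − α + α/Γ(α).

Truncating the GL discretization of the Atangana–Baleanu fractional
integral at four terms yields the mask weights

    ρ0 = 1/M,  ρ1 = α/(2M),  ρ2 = (α³−α²)/(2M),  ρ3 = (α²−α⁴)/(6M),

with signs (+, +, −, +) on (0, 1) and the classical limit (1, ½, 0, 0) at
α = 1. The GL step is fixed at h = 1 — the masks index unit pixel
offsets, so the continuum h → 0 limit is not taken. ρ2 and ρ3 are computed
and exposed but the shipped mask tables use only ρ0 and ρ1. The
Mittag-Leffler function is evaluated by direct series summation
(tolerance 1e−14, ≥ 10 terms, 10 000-term cap); it is used for validation
only, never in the per-pixel path, so no large-|t| algorithm is needed.

## Masks

Four families are built from (ρ0, ρ1), all applied as **correlation**
(no kernel flip — a flip would silently swap the named directions):

* **directional** (3×3): ρ0 at the center, ρ1 at the neighbor one step
  along one of eight compass directions ("positive y" = up, row −1).
* **scaled** (3×3): the weight spread over the neighborhood — the three
  cells on the leading side get ρ1/3 each, the remaining cells share ρ0
  in fifths.
* **bidirectional** (3×3): difference of two opposite scaled masks;
  antisymmetric and exactly zero-sum, hence zero response on constants.
* **composite** (5×5): the published combination of the eight directions;
  180°-antisymmetric (w[i,j] = −w[4−i,4−j]) and zero-sum for every α.

Every family has two variants. `canonical` (default) follows the
construction rules above, for which the claimed invariants (rotation
closure among the eight directions, zero DC) hold exactly. `as_printed`
reproduces the source tables verbatim, including their irregularities:
the scaled tables place their zero cell opposite the direction rather
than at the center; one bidirectional block mixes ρ1/5 and ρ0/3
denominators unlike every other block; two scaled grids missing from the
published layout (a duplicated header) are reconstructed by the rotation
rule — a transcription repair flagged as such, not an editorial fix. The
composite 5×5 grid is printed consistently and is identical in both
variants.

Mask entries are carried symbolically as exact rational multiples
c0·ρ0 + c1·ρ1 (`fractions.Fraction`) and evaluated to floats only at
construction, so antisymmetric pairs cancel to machine zero and the
zero-DC property survives floating point.

## Enhancement pipeline

1. **Gradient map**: Euclidean magnitude of 3×3 Sobel x/y correlations,
   replicate padding. Sobel is used because it is the integer-order
   reference operator the method is benchmarked against.
2. **Segmentation**: t1 = mean gradient magnitude; t2 = mean of gradients
   strictly above t1 (t2 = t1 if none). Smooth ≤ t1 < texture ≤ t2 <
   edge. This iterated-conditional-means reading is the simplest
   construction consistent with "two criteria from the mean of the
   gradient image"; it is a deliberate interpretation, documented here.
3. **Response**: one mask set per region order (defaults α = 0.4 / 0.6 /
   0.8 for smooth / texture / edge; the ordering constraint
   α_smooth ≤ α_texture ≤ α_edge is enforced). The response of a mask is
   its DC-removed detail signal — raw correlation minus the mask's entry
   sum times the image. For zero-sum kinds this subtracts nothing; for
   the directional kind it removes ρ0+ρ1, leaving the pure directional
   difference ρ1·(shifted − image), which vanishes as α → 0⁺ so the
   filter degenerates to the identity. Multi-mask kinds reduce over
   masks by summation (default) or by signed maximum magnitude.
4. **Combination**: `enhanced = clip(image + λ·response, 0, 255)` with
   intensity factor λ (default 1). The additive high-boost form is chosen
   because replacing pixels by the raw response of a zero-sum kernel
   would blacken smooth regions; the add-and-clip form leaves constants
   exactly fixed and makes λ = 0 the exact identity.

The pipeline is float64 end to end; quantization to 8 bits (round half
away from zero after clipping) happens only at file write, so metrics on
written files match in-memory values to within half a gray level.

Per-modality single-order presets: ultrasound 0.45, X-ray 0.55, CT 0.6,
MRI 0.6, within the usable 0.3–0.9 envelope; the adaptive triple
0.4/0.6/0.8 places each region at the middle of its recommended band.
Region-adaptive orders are implemented at region granularity only; a
continuously per-pixel-varying α has no published construction rule and
is deliberately out of scope.

### Degenerate and boundary behavior

* Padding: replicate (default) or reflect; the choice only affects a
  border of half the mask width.
* A mask larger than the image is rejected.
* α is validated to (0, 1]; the α → 0⁺ identity holds for the
  directional kind at rate O(α). For zero-sum kinds the response does
  *not* vanish as α → 0⁺ (the entries are multiples of ρ0 → 1), so they
  are identity only on constant images — an algebraic property of the
  published coefficient set, not an implementation choice.
* The antisymmetric bidirectional response to a clean step is equal on
  both flanking columns (the trailing weight ρ0/5 exceeds the leading
  ρ1/3 for all α ≤ 1), so it translates intensity at edges rather than
  steepening them: cross-edge gradient is preserved exactly in the
  non-clipping regime, while the composite 5×5 mask strictly increases
  it. Saturation at 0/255 can reduce either.

## Metrics

MSE and PSNR (10·log₁₀(255²/MSE), +∞ sentinel at MSE = 0) follow the
standard definitions. SSIM uses unweighted square sliding windows
(default 8×8, stride 1, averaged over all windows; no Gaussian
weighting), stabilizers C1 = (0.01·255)², C2 = (0.03·255)², C3 = C2/2,
and unit exponents, under which the three components collapse to the
familiar single-fraction form. Variance and covariance are computed with
the same moment formula (E[xy] − μμ) so identical images score exactly 1
in every window.

CNR has no universal definition; this package's convention is
`|mean(ROI) − mean(background)| / std(background)`. Published CNR numbers
elsewhere may use other conventions and are not comparable without the
same ROI choices.

## Phantom generator

The generator produces deterministic (seeded, bit-reproducible) grayscale
scenes with the statistical features of the target imagery and exact
ground-truth region labels:

* `three_region` (default): a low plateau (level 50) and a high plateau
  (level 230) joined by a two-pixel ramp step, with a band-limited-noise
  texture patch (3×3 moving-average of uniform noise, RMS amplitude 25,
  64×32 pixels) on the low plateau. The ramp makes the edge band that a
  3×3 Sobel flags coincide with the strong-response zone of the 5×5
  mask. Ground truth: the three ramp columns are edge, the patch is
  texture, everything else smooth.
* `step_edge`: a sharp single-column step (edge band = the two flanking
  columns).
* `checkerboard`: 8-px blocks; block-boundary bands are edge.
* `concentric`: 12-px rings; ring boundaries are edge.

Noise models (applied last, clipped to [0, 255]): additive Gaussian
(CT/X-ray-like; default sd 5), multiplicative speckle `I·(1+N(0, sd²))`
(ultrasound-like; sd is relative), and Rician magnitude noise
`√((I+n₁)² + n₂²)` (MRI-like). sd = 0 is the identity for all models.

Defaults were chosen once, as the generator's definition of a realistic
scene: plateau contrast 180 is in the range of bone/soft-tissue or
fluid/tissue steps on an 8-bit scale; texture RMS 25 is strong fine
texture; Gaussian sd 5 is mild sensor noise. With these settings the
mean-threshold segmentation recovers the ground truth on ≈ 92–93 % of
pixels across seeds, the default enhancement raises texture-region
variance roughly tenfold and moves the smooth-region mean by < 1 %.

What the phantoms do **not** emulate: anatomy, MRI k-space sampling,
ultrasound beam physics, partial-volume effects, spatially varying noise.
Passing tests on phantoms therefore demonstrate the *operator contracts*
(range safety, region behavior, metric correctness), not clinical image
quality.

## Problem sizes and numerical tolerances

Tests and the acceptance script run at the scale the method targets:
128×128 phantoms for pipeline behavior (20 seeds for segmentation
recovery), 8×8–32×32 images for the brute-force convolution, metric and
full-pipeline scalar oracles (agreement to 1e−9), and 10–100-point α
grids for coefficient and mask-algebra properties (zero-DC to 1e−12,
GL-recurrence agreement to 1e−12). The scalar oracles are pure-Python
double-loop reimplementations kept independent of the vectorized code
paths.

## Known limitations

* The `as_printed` bidirectional masks are not all zero-sum (the printed
  tables are internally inconsistent); only the canonical variant
  guarantees zero response on constant regions.
* ρ2/ρ3 are exposed but unused by the shipped masks; larger truncations
  and masks beyond 5×5 are out of scope.
* Color images are reduced to luma on read; there is no per-channel
  processing.
* The Mittag-Leffler routine targets moderate real arguments only.
* CNR uses this package's convention (above) and is not comparable to
  values computed with other ROI or formula choices.
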