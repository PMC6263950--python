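# Methods

## Signal model and optical-constant extraction

A scan is the sampled electric field E(t) of a single-cycle THz pulse, on a
uniform axis of 40 ps at 0.02 ps step (frequency resolution 0.025 THz,
Nyquist 25 THz). The emitter model is a differentiated Gaussian,
E(t) ∝ −(t−t₀)·exp(−(t−t₀)²/2τ²) with τ = 1/(2π·0.6 THz) ≈ 0.265 ps, whose
amplitude spectrum |ω|·exp(−ω²τ²/2) peaks at 0.6 THz and retains 52% / 13%
of its peak at the 0.2 / 1.6 THz band edges — comfortably above the 1%
floor the extraction needs.

Traces are Fourier-transformed with a rectangular window by default
(synthetic traces decay to zero well inside the window; a Hann taper is
available for truncated data), zero-padded to the next power of two ≥ 4× the
trace length, and interpolated linearly onto a fixed analysis grid
(0.2–1.6 THz, 0.01 THz step, 141 bins, closed at both ends). The phase
convention is E˜(ω) = A·e^(−iφ), so a delay adds positive φ. Phase is
unwrapped upward from the lowest non-DC bin; the residual whole-turn offset is
removed by fitting a line to the phase where the amplitude exceeds 10% of
its peak and subtracting 2π·round(intercept/2π) — the physical phase of a
delayed pulse extrapolates to zero at DC.

The absorption coefficient is computed literally as α = (1/d)·ln(A_ref/A_sam)
on the field amplitude, without the conventional factor 2 between field and
intensity coefficients; the slab forward model applies exp(−α·d) to the
field so that forward and inverse are one consistent pair (the round trip
recovers a 1 mm slab with n = 1.53, α = 10 cm⁻¹ to machine precision;
the acceptance tolerance is |Δn| ≤ 10⁻³, |Δα| ≤ 0.1 cm⁻¹ over 0.4–1.4 THz).
Whether a given instrument's α is a field or intensity coefficient is a
convention choice; all rates in this package are invariant to it because
the same convention is used throughout.

Replicate scans are averaged pointwise in the time domain (5 scans per
pellet by default), which empirically reduces the mean-squared field noise
by the expected factor ≈ 5.

## The synthetic pellet population

Each pellet is a homogeneous slab, thickness 1 mm, with

    n(f) = n₀ − s_n·(f − 0.9 THz),      α(f) = a₀ + s_a·f + c·(f − 0.9)²

and per-pellet parameters drawn from class-conditional Gaussians. The class
means are ordered n(worm-eaten) < n(moldy) < n(germinated) < n(normal)
within 1.50–1.56, and absorption levels are ordered the same way (normal
wheat both densest and most absorbing). Absorption curves are smooth and
monotone — milled-grain pellets show no resonant fingerprints in this band —
so all class information lies in levels, slopes and their covariance.

Two structural choices make the population more than four displaced
Gaussian blobs:

- **Heterogeneous defect classes.** Mold and insect damage progress by
  degrees, so the two defect classes carry larger between-pellet spreads
  than sound wheat (e.g. σ(a₀) = 0.65 vs 0.30 cm⁻¹).
- **Covariance orientation as the discriminating cue.** Within the moldy
  class, index level and absorption level are strongly positively
  correlated (ρ = 0.98): fungal biomass densifies and absorbs jointly.
  Within the worm-eaten class the coupling has the opposite sign
  (ρ = −0.98): hollowed kernels decouple residual density from absorbance.
  The same opposition is placed between index level and index slope
  (ρ = ±0.95). Where the two defect classes' level distributions overlap,
  they remain separable — but only by a classifier that can use orientation,
  i.e. a curved decision boundary. This is what lets the RBF kernel
  reproducibly outrank the linear one, mirrors the qualitative model
  ordering the pipeline exists to study, and is invisible to each
  single-modality sub-classifier in exactly the way that keeps decision
  fusion slightly behind feature fusion.

Measurement noise is additive white Gaussian on the field, σ = 0.002 of the
unit reference peak per scan (≈ 54 dB single-scan dynamic range, improved by
the 5-scan average), applied independently to reference and sample scans.

What the generator does **not** emulate: Fabry–Pérot etalon echoes in thin
pellets, scattering losses, water-vapor absorption lines, detector response,
drift between reference and sample acquisition, and any within-class
multimodality from discrete degradation stages. Passing tests therefore
demonstrate the correctness and statistical behaviour of the pipeline on a
population with realistic first- and second-order structure — not
instrument-level fidelity, and not performance on real grain.

## Feature extraction and scaling

PCA is fitted per modality on training spectra only (centering, no variance
scaling: bins of one modality share units). Component signs are fixed so
each loading's largest-magnitude element is positive. Feature-layer fusion
concatenates absorption-then-refraction scores (8 + 10 components by
default; the decision-layer sub-classifiers use 10 + 8 — both counts are
configuration).

Score blocks are put on a common footing by dividing each modality's block
by its root total training-score variance ("block normalization"). A
per-feature z-score was rejected deliberately: the leading component of each
modality carries ≥ 97% of the variance here, and z-scoring inflates the
near-zero-variance trailing components into full-variance noise dimensions
that dominate kernel distances — the RBF search then retreats to its
smallest grid gamma and degenerates into an inferior linear machine. Block
normalization achieves the purpose of standardization (one gamma meaningful
across modalities) while preserving the variance decay that makes kernel
distances informative. For standalone use of the classifier module on
arbitrary features, per-feature z-scoring remains the default
(`SvmConfig.scale`).

## Classification

SVMs use a one-vs-one multiclass scheme with pairwise-coupled Platt
calibration for probability outputs. Hyper-parameters (γ, C) are selected
on logarithmic grids 2⁻⁶…2⁶ by stratified 5-fold cross-validation on the
training set, ties broken toward smaller C then smaller γ. The polynomial
kernel is the inhomogeneous form (degree 3, coef0 = 1); the homogeneous
variant is degenerate on centered features.

For the decision-layer sub-classifiers the grid is scored by the CV accuracy
of the argmax of the *calibrated probabilities* rather than the hard
decision rule. The two can diverge: at very small C the margins compress,
the decision rule stays accurate, but pairwise-coupled probabilities go
nearly uniform — and a sub-classifier is only as good as the probability
vector the evidence combination consumes. Feature-layer models, whose
output is the hard label, keep plain accuracy scoring.

## Evidence combination

Mass functions live on the four singletons plus the whole frame U; no other
subsets carry mass, so Dempster's rule reduces to closed-form sums
(conflict K = Σ_{i≠j} m₁ᵢm₂ⱼ; combined singleton i ∝ m₁ᵢm₂ᵢ + m₁ᵢu₂ + u₁m₂ᵢ;
combined U ∝ u₁u₂). A property suite checks commutativity, associativity,
vacuous neutrality, K ∈ [0,1), normalization, reinforcement of repeated
evidence, and exact agreement with an exhaustive enumeration over focal-set
pairs. Total conflict (K = 1) raises an error and the sample is deferred.

The belief weighting of each source is implemented as classical reliability
discounting with reliability = the sub-classifier's cross-validated training
accuracy, so the weaker modality cedes mass to U rather than asserting
wrong classes confidently. Decision thresholds default to ε₁ = 0.1 (minimum
lead of the winner over the runner-up) and ε₂ = 0.3 (maximum tolerated
ignorance mass); both are configuration, since the operating point of the
deferral rule is application policy, not statistics. For 4-way recognition
tables, deferred samples are scored by the argmax of the combined mass and
the deferred count is reported alongside.

## Evaluation

Confusion matrices use the fixed class order normal / germinated / moldy /
worm-eaten. Recognition rates are 100·diagonal/row-sum per class and
100·trace/total overall, displayed at two decimals with round-half-up
(matching the convention by which 20/21 prints as 95.24). Rates are kept
unrounded internally. Model comparison sorts by overall test rate, stable
under ties.

## Study conditions and problem sizes

The default run generates 60 pellets per class (240 total), 5 scans each,
splits 2:1 (160 train / 80 test, stratified), searches the full 13×13 grid
per kernel, and completes in well under a minute on one CPU. The unit-test
fixtures use 6 pellets per class and reduced grids, chosen to exercise every
code path at desk scale. With an 80-sample test set, one sample is 1.25
percentage points; between-model differences of that order at a single seed
are noise, which is why the end-to-end check asserts the recognition band
(≥ 90%) and the ordering of the RBF feature-fusion model (highest or tied)
rather than exact rates.

## Known limitations

- The split is stratified by default; the published per-class test counts
  (22/14/21/23) evidently came from an unstratified draw, which is available
  via configuration but makes small classes noisier.
- Whether PCA should see all samples or training only is ambiguous in the
  tables this package mirrors; training-only is implemented as the
  leakage-free choice, which makes test rates honest but slightly lower.
- Reliability discounting via CV accuracy is one defensible reading of
  "belief function of the classifier"; alternatives (held-out calibration,
  class-conditional reliabilities) would shift the DS operating point.
- The ε-thresholded decision rule's deferral behaviour depends on
  calibration quality; with few training samples per class, Platt
  calibration is the weakest link.
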