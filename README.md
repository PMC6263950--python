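# thzwheat

Wheat-quality recognition from terahertz time-domain spectra by multi-source
information fusion.

Stored wheat degrades in characteristic ways — germination, mold growth,
insect damage — and each changes the grain's dielectric response in the
0.2–1.6 THz band. A transmission THz-TDS measurement of a pressed wheat
pellet yields two optical constants simultaneously: the absorption
coefficient α(f) from the amplitude ratio of sample to reference pulse, and
the refractive index n(f) from their phase difference,

    α(f) = (1/d) · ln(A_ref / A_sam)                      [cm⁻¹]
    n(f) = 1 + (φ_sam − φ_ref) · c / (ω·d)

with d the pellet thickness (1 mm by default). Neither spectrum shows sharp
resonances for milled grain, so classification rests on chemometrics:
per-modality PCA scores feed kernel support-vector machines, and the two
optical modalities are fused two ways:

- **feature-layer fusion** — the absorption scores (8 components) and
  refraction scores (10 components) are concatenated into one 18-dimensional
  vector classified by a single SVM (RBF, linear or polynomial kernel,
  hyper-parameters grid-searched by cross-validation);
- **decision-layer fusion** — one RBF-SVM per modality produces calibrated
  class probabilities, which become basic probability assignments over the
  frame Θ = {normal, germinated, moldy, worm-eaten, U} by reliability
  discounting (singleton mass = reliability × probability, remainder on the
  ignorance element U). Dempster's rule combines the two sources,

      K      = Σ m₁(Aᵢ)·m₂(Aⱼ)   over disjoint singleton pairs Aᵢ ∩ Aⱼ = ∅
      m_c(A) = Σ m₁(Aᵢ)·m₂(Aⱼ) / (1 − K)   over pairs with Aᵢ ∩ Aⱼ = A

  and a thresholded rule accepts the leading class A₁ only when
  m_c(A₁) − m_c(A₂) > ε₁, m_c(U) < ε₂ and m_c(A₁) > m_c(U); otherwise the
  sample is flagged *uncertain*.

Because no public archive of grain THz spectra exists, the package ships a
physically explicit simulator: each virtual pellet is a homogeneous slab with
class-conditional (n, α) profiles, propagated through the exact frequency-
domain transfer function and "measured" with 5 noisy replicate scans. The
whole pipeline — simulate → extract → PCA → SVM → fuse → evaluate — is
therefore reproducible end to end from a single seed.

## Worked example

```python
from thzwheat import load_config, run_all

report = run_all(load_config(None, seed=1))
for row in report["comparison"]:
    print(f"{row['model']:<24} {row['overall_rate']:>6.2f}")
```

prints the overall test-set recognition rates (percent, 80 test samples out
of 240, split 2:1):

```
rbf_feature_fusion        97.50
ds_decision_fusion        96.25
poly_feature_fusion       95.00
linear_feature_fusion     93.75
```

Reading: with 60 pellets per class, the RBF feature-fusion model mislabels
2 of 80 held-out pellets (97.5%); Dempster-Shafer decision fusion of the two
single-modality RBF classifiers reaches 96.25% with 0 samples deferred as
uncertain; the linear and polynomial feature-fusion models trail. Errors
concentrate in the moldy/worm-eaten pair, whose level distributions overlap
and which differ mainly in how index and absorption co-vary — structure a
nonlinear kernel can use. Training-set rates for the RBF and DS models are
100%. The same pipeline is scriptable per stage:

```
thzwheat simulate --out raw --seed 1
thzwheat extract --in raw --out spectra --band 0.2:1.6
thzwheat run-all --out results --seed 1
```

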