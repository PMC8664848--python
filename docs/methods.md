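# Methods

This note records the mathematical choices behind `psqi-geo` in enough
detail to re-derive the implementation.

## 1. Problem setting

Input: N geo-referenced samples, each with M measured water properties
(concentrations, hardness, pH). Output: continuous maps of every property
with calibrated uncertainty, plus a scalar quality index per location.
Typical problem sizes are N in the hundreds and M up to ~20; everything is
designed to run on a single CPU core at that scale.

## 2. Coordinates

Longitude/latitude are projected to metres with a transverse Mercator
projection (WGS84, UTM zone of the data centroid unless an EPSG code is
given). The projection uses the 6th-order Krüger series with a fixed-point
inversion of the conformal latitude; round trips are accurate to well below
1e-6 degrees, and the forward map agrees with an independently coded
classical series to centimetres inside a zone. Projected coordinates are
min–max scaled to the unit square of the training extent, so kernel
length-scales are dimensionless fractions of the surveyed region.

## 3. Measurement warping

Gaussian process regression assumes Gaussian residuals, which bounded,
non-negative, often-censored measurements violate. Each property y is
warped by a fixed monotone map:

1. `u = y / L`, where the scale `L` is 10× the larger of the training
   column maximum and the regulatory upper bound. The factor 10 keeps all
   realistic values in the interior of (0, 1) so that step 2 is
   well-conditioned, while still pinning the scale to physically meaningful
   magnitudes. pH is a special case: its hard physical support [0, 14] is
   used directly, with no inflation.
2. `t = Φ⁻¹(u)`, the inverse standard-normal CDF. Exact zeros (detection
   limit) are replaced by 1e-10 first; at prediction time `u` is clamped to
   [1e-10, 1 − 1e-12] so extrapolated values never produce infinities.
3. min–max normalization of `t` by the training extremes, giving the warped
   value `z ∈ [0, 1]` on the training data.

The warp is strictly increasing, so for any interval event
`P(a ≤ y ≤ b) = P(warp(a) ≤ z ≤ warp(b))` exactly. This is what lets the
index integrate Gaussians in warped space and still report probabilities
about original measurement units. The inverse warp is analytic and round
trips to ~1e-15 relative error.

## 4. The multi-task Gaussian process

Stack the warped data column-major by task: `ȳ = vec(Zᵀ)` of length NM.
The joint covariance is

```
Σ = K^f ⊗ K^x + D ⊗ I_N
```

- `K^x` — spectral-mixture kernel over scaled coordinates:
  `k(τ) = Σ_q w_q Π_p exp(−2π² τ_p² v_qp) cos(2π μ_qp τ_p)`.
  Each component is a Gaussian in frequency space; mixtures of them are
  dense in stationary kernels. The component length-scale convention is
  `ℓ = 1 / (2π√v)`; length-scales are confined to [0.1, 100] scaled units
  (roughly: no structure finer than a tenth of the region, no pretending to
  see structure 100× larger than it).
- `K^f = B·Bᵀ + diag(v)` — low-rank plus diagonal task covariance
  (M×r loadings `B`, r ≪ M). Off-diagonal entries encode how properties
  co-vary; the implied correlation matrix is a model output of interest in
  its own right.
- `D = diag(σ²_1 … σ²_M)` — per-task noise.
- Mean: a full quadratic polynomial `c0 + c1x₁ + c2x₂ + c12x₁x₂ + c11x₁² +
  c22x₂²` per task.

Prediction at x* conditions the joint Gaussian:

```
μ̂(x*) = μ(x*) + (K^f ⊗ k*)ᵀ Σ⁻¹ (ȳ − μ̄)
Σ̂(x*) = k(x*,x*)·K^f − (K^f ⊗ k*)ᵀ Σ⁻¹ (K^f ⊗ k*)
```

Rather than factorizing the dense NM×NM matrix, the solve exploits the
Kronecker structure: with `K̃^f = D^{-1/2} K^f D^{-1/2} = U_f Λ_f U_fᵀ` and
`K^x = U_x Λ_x U_xᵀ`, the eigenvalues of the symmetrized Σ are
`λ_f λ_x + 1`, and both the NM-vector solve and the per-point predictive
covariance reduce to O(NM) work after an O(N³ + M³) precomputation. A
dense fallback path exists and the two agree to ~1e-14; the acceptance
suite pins this equivalence.

## 5. Hyper-parameter estimation

The negative log marginal likelihood is minimized by Adam (300 iterations,
learning rate 0.1 by default) on a raw parameter vector: softplus maps for
weights, task diagonal and noise; a scaled logistic for the length-scales
(boxes become smooth, so no clamping or projected gradients); loadings,
spectral means and mean coefficients free. The gradient is fully analytic.
The generic identity

```
d NLL = ½ tr(Σ⁻¹ dΣ) − ½ αᵀ dΣ α − dμ̄ᵀ α,   α = Σ⁻¹(ȳ − μ̄)
```

is evaluated with Kronecker-aware contractions so no NM×NM intermediate is
ever formed: for spatial-kernel parameters the trace term contracts the
blocked Σ⁻¹ against `K^f`, for task parameters against `K^x`. Central
finite differences confirm the gradient to ~1e-9 relative error.

Initialization is data-driven and seeded: mixture weights share the total
variance, the initial length-scale is 0.3 (about a third of the region),
spectral means are drawn uniformly up to the Nyquist frequency of the
median nearest-neighbour spacing, loadings and noise start at fractions of
the per-task variance, and the constant mean coefficients start at the task
means. Adam returns the best iterate seen, so the reported objective never
degrades with extra iterations. Fits are deterministic given the seed.

## 6. Model selection and masking

The component count Q and rank r are chosen on a grid by cross-validation:
five seeded random 80/20 splits by default (a disjoint k-fold mode is
available). The scaler and the warp are refitted on each training fold —
the test fold must not leak into the warp extremes. Scores are R² = 1 −
MSE/Var per property **in original units** (predictions inverse-warped
first); the warp is nonlinear, so warped-space R² would measure something
else. A property is masked from the index only if *every* candidate model
fails to beat its mean (max split-averaged R² < 0). The winner maximizes
mean R² over kept properties; exact ties break toward the simpler model
(smaller Q, then smaller r).

## 7. The index and its confidence

For regulated property i with admissible range [b_i^L, b_i^U], the marginal
of the M-variate warped predictive Gaussian is univariate Gaussian, so

```
p̂_i = Φ((b̃_i^U − m_i)/s_i) − Φ((b̃_i^L − m_i)/s_i)
```

with warped bounds b̃ — closed form, no quadrature. The index is
`PSQI = Σ_i w_i p̂_i ∈ [0, 1]` with softmax weights
`w_i ∝ exp(max(R²_i, 0))`. Properties whose cross-validated R² is
non-positive are served from the training-set marginal instead (dataset
mean and variance in warped space, correlations zeroed) — the model has
demonstrated it cannot localize them, so the index falls back to the
honest climatological answer rather than a confidently wrong one. The
fallback operates in warped space because that is where the dataset
moments are well-defined Gaussian summaries.

The confidence value re-evaluates the same weighted mass with each mean
moved to the midpoint of its admissible range: it equals the index exactly
when the prediction already sits at the midpoints, tends to 1 as the
predictive spread vanishes and to 0 as it blows up, and is invariant to
where the actual mean lies. Index and confidence are deliberately
decoupled: "the water is bad here" can be said with high confidence.

A `space="naive"` mode integrates against original-unit bounds using an
inverse-warped ±1 sd interval as a pseudo-Gaussian spread. It exists to
quantify how much the warp matters; the warped mode is the correct,
probability-preserving default.

## 8. Standards table

The packaged table carries 21 properties with normative ranges; one-sided
standards get an implicit lower bound of 0. Calcium, potassium and
bicarbonate carry no normative range and are modeled but never enter the
index. Iron appears in some regulatory variants at 1.0 mg/L instead of
0.3 mg/L; the packaged default is 0.3 and `default_standards(overrides=
{"Fe": (None, 1.0)})` switches variants explicitly rather than silently.

## 9. Synthetic study and its limits

The generator draws latent fields from the *model family itself* (SM-kernel
GP × rank-2 task covariance, linear trends) and squashes them through
`y = L·Φ(g)`, adding 10% noise variance and censoring the lowest decile of
nitrate to exact zeros. Defaults (N=200, M=4, true Q=1, r=2, seed 7)
define the reference study. Because the data-generating process is inside
the model family, recovery benchmarks measure the estimation pipeline, not
model misspecification; real surveys will be harder. The censored nitrate
column is the deliberate exception: the zeros make its warped distribution
bimodal and genuinely non-Gaussian, and the pipeline responds the way it
should — cross-validation flags it and the index stops trusting the model
for it. The benchmark asserts held-out R² > 0.4 on kept parameters, task
correlations recovered to MAE < 0.25, and Pearson ≥ 0.5 between the index
and the directly measured fraction of parameters in bounds.

## 10. Map products

Prediction grids are inclusive lattices in projected metres (default
spacing 100 m), optionally clipped to a polygon (boundary included). Map
tables carry, per point: inverse-warped predictive means (a median-type
central estimate in original units), warped-space standard deviations, the
index, its confidence, and every per-property marginal. Batch size does
not affect values, and reruns from the same serialized model are
byte-identical.
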