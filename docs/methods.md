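# Methods

## Model

At each voxel *v* of a masked 3D image domain, the across-subject
distribution of intensities Y(v) is modelled as skew-normal in the centred
parameterisation (CP): mean μ(v), standard deviation σ(v) and standardised
third-moment skewness γ(v), with |γ| < c_γ = √2(4−π)/(π−2)^{3/2} ≈ 0.99527.
The mean carries the covariates linearly,

    μ_i(v) = β₀(v) + β_age(v)·age_i + β_sex(v)·sex_i + β_int(v)·age_i·sex_i,

with sex coded female = 1, male = 0 (so β_age is the male slope and
β_age + β_int the female slope; the coding is recorded in fit metadata).
Age enters raw, in years — the intercept map is therefore the extrapolated
mean at age 0 and the predicted-mean surface, not β₀ itself, is the
interpretable quantity. σ and γ are constant across subjects at a voxel; no
covariates enter scale or shape.

The CP relates to the direct parameterisation (DP: location ξ, scale ω,
shape α) through the standard bijection: with b = √(2/π),
δ = α/√(1+α²), μ_z = bδ, one has μ = ξ + ωμ_z, σ = ω√(1−μ_z²),
γ = ((4−π)/2)·μ_z³/(1−μ_z²)^{3/2}, inverted in closed form via
t = (2γ/(4−π))^{1/3}. The CP is used throughout because its likelihood is
closer to quadratic and its estimates less correlated than the DP's, and
because (μ, σ, γ) are what a normative chart reports.

A subject's image is referenced to the fitted population by the probability
integral transform U(v) = F_SN(Y(v); μ(v), σ(v), γ(v)) followed by
z(v) = Φ⁻¹(U(v)). U = 0.5 (z = 0) marks the population median, and a given
z value has the same tail probability at every voxel — the property that
makes z-maps comparable across brain regions where raw intensities are not.

## Numerical core

- **CDF.** F_SN is evaluated in DP form as Φ(z) − 2·T(z, α) with Owen's T
  function (`scipy.special.owens_t`). This is exact, vectorised, and fast
  enough for whole-mask maps (~10⁶ evaluations in a few seconds); absolute
  accuracy is limited only by ~10⁻¹⁵ cancellation in the extreme tails,
  far below the U-clipping threshold.
- **Quantiles.** Vectorised bisection (60 steps on μ ± 12σ) with three
  Newton polishing steps; round-trip accuracy in probability is below 1e-9.
- **Sampling.** The two-normal representation
  X = ξ + ω(δ|Z₀| + √(1−δ²)Z₁); seeded `numpy.random.Generator`.
- **U-clipping.** U is clipped to [1e-12, 1−1e-12] before Φ⁻¹ so z-maps are
  finite; |z| therefore saturates near 7.03. Clip events are rare for
  model-consistent data and are irrelevant to median-based summaries.

## Estimation

Per-voxel maximum likelihood in CP. The optimiser (L-BFGS-B) works on the
unconstrained parameters (β, log σ, atanh(γ/γ_max)) with γ_max = 0.99·c_γ,
keeping iterates strictly inside the skewness bound. Starting values are the
OLS solution, the residual SD, and the residual moment skewness clipped to
±0.95·c_γ. Convergence tolerance 1e-8 on the objective, at most 500
iterations, two jittered restarts on failure; if all attempts fail the voxel
falls back to the Gaussian (γ = 0) OLS fit and is flagged. Fits whose γ
reaches the transformed boundary are kept at ±0.99·c_γ and flagged. Voxels
are fitted independently; per-voxel failures are counted in metadata, never
fatal.

Near γ = 0 the CP maximum-likelihood skewness estimate has asymptotic
variance ≈ 6/n (the moment-skewness rate), i.e. SE ≈ 0.17 at n = 200. This
sampling floor, not the optimiser, dominates the accuracy of recovered γ
fields at realistic cohort sizes; similarly, the raw-age design makes the
intercept an extrapolation to age 0 whose SE is an order of magnitude larger
than the in-range mean's. Recovery experiments on the phantom reproduce both
floors (see Calibration below).

## Grid fitting and interpolation

Fits run only on a regular lattice of in-mask voxels (default spacing 8 mm),
anchored at the mask bounding-box minimum corner. Each grid-valued field is
carried to the rest of the mask by Gaussian RBF interpolation with a
polynomial offset, solving the bordered system

    [H 1; 1ᵀ 0]·(b, b₀) = (Z, c),  H_jl = exp(−d_jl²/2ε²),

with distances in mm. The border right-hand side c defaults to 1 (a
sum-to-one condition on the weights); the conventional polynomial-
orthogonality variant c = 0 is a config switch. Both yield exact
interpolation at the centres (verified to 1e-8); they differ only in how the
constant offset is apportioned, and neither reproduces a constant field
exactly off-grid — the deviation is a diagnostic, not an error. Under the
sum-to-one default a constant field c₀ is reproduced off-grid up to
(c₀ − b₀)·(1 − Σ bₗ h) terms that vanish as ε grows.

Kernel width defaults to ε = ⅔·spacing (5.33 mm at 8 mm): narrow enough
that the system stays well conditioned (condition number grows monotonically
with ε; solves abort above 1e12 unless a small ridge is requested), wide
enough to avoid the bed-of-nails regime in which the interpolant collapses
to b₀ between centres. Grid voxels always keep their fitted values exactly.

σ is interpolated on its raw scale and floored at 1e-6 × the grid median
(the alternative, interpolating log σ, changes results negligibly at these
smoothness levels and makes the interpolated field harder to compare with
the fitted one); γ is clamped to ±0.99·c_γ. Both clamp counts are logged.
No special boundary treatment is applied for Runge-type edge effects at
moderate spacing; edge voxels simply sit further from their nearest centres.

### z-map route

Two routes to a full-mask z-map exist: (a) interpolate the parameter
functions once, then transform every voxel, and (b) compute z at the grid
voxels and interpolate the z-field per subject. Route (b) assumes the
z-field itself is spatially smooth, which holds only when the image noise is
spatially correlated. The default phantom generates voxelwise-independent
noise (the model being fitted is the marginal per-voxel law), so route (a)
is the package default for scoring and calibration; route (b) is provided as
`normative.zmaps_via_grid` for data with genuinely smooth residual fields.

## Deviation index

u_q^abs = mean of the absolute z-values strictly above their empirical
q-quantile (linear interpolation of order statistics; q = 0 returns the
overall mean of |z|; ties at the maximum fall back to ≥ membership).
Default q = 0.9999 averages roughly the top 0.01% of |z| — on a 24k-voxel
mask, the two or three most extreme voxels. Absolute values are used because
disease-like deformation pushes ventricular voxels up and cortical voxels
down simultaneously; one-sided variants would halve the signal.

## Phantom design

The generator emulates the statistical structure of cross-sectional TBM-like
cohorts, not anatomy:

| parameter | default | rationale |
|---|---|---|
| domain | 40³ voxels, 1 mm | large enough for a 5³ 8 mm grid; minutes-scale tests |
| brain | sphere r = 18 mm | ~24k mask voxels |
| baseline mean | 1000 | template-volume convention |
| ventricle elevation | +100 | expanded-volume region |
| σ baseline / ventricle | 25 / ×2.5 | spread inflates with mean |
| γ baseline / ventricle | 0.2 / 0.7 | mildly right-skewed everywhere, strongly in the ventricle |
| age slopes | +2.0 in ventricle, −0.6 in shell (units/yr) | expansion with age inside, shrinkage outside |
| sex, interaction | 5.0, 0.3 | small nonzero effects |
| ages, sex ratio | U(55, 90), 0.5 | adult ageing cohort |

All fields are smooth by construction: the ventricle profile is a Gaussian
with per-axis SD equal to the ventricle radii, the cortical-shell profile a
radial Gaussian of width 0.15·r_brain, and the baseline variation a
Gaussian-filtered random field (6 mm length-scale, amplitude 5). σ and γ are
monotone functions of the same mean-elevation field, which gives the
positive mean–SD and mean–skewness coupling by construction (rank
correlation 1 over the mask). Voxels are sampled independently given their
parameters — exactly the marginal law the fitting stage assumes; an optional
smoothing flag correlates the noise for realism but is off by default and
excluded from the validation experiments. What passing tests show is that
the workflow recovers its own generating process at realistic n; they say
nothing about registration artefacts, scanner effects or spatial dependence
in real data.

Disease injection adds k·σ(v) inside the ventricle ellipsoid and subtracts
0.5·k·σ(v) in the cortical shell, mimicking ventricular enlargement balanced
by cortical shrinkage.

## Calibration experiments and known floors

The validation study (200 training subjects, 50 held-out, default phantom,
8 mm grid) is the problem size used throughout the tests and the acceptance
script; it runs in seconds while keeping per-voxel fits at a realistic
cohort size.

- σ fields are recovered to ~2–3% of their range; pure interpolation error
  of the true fields is 1–2% of range for all parameters.
- γ recovery is bounded by the √(6/n) sampling floor: mask-wide MAE ≈ 0.13
  at n = 200, dominated by estimation noise, not interpolation.
- β₀ (the age-0 extrapolated intercept) carries a per-voxel SE of ~18
  intensity units at n = 200 under the raw-age design; its mask-wide median
  absolute error (~9–13 units depending on seed) reflects that floor. The
  in-range predicted mean is accurate to a few units.
- z-map calibration is assessed at the typical voxel: the median across mask
  voxels of the per-voxel mean-z and SD-z over the training cohort (medians,
  because individual voxels fluctuate with SE 1/√n plus an off-grid
  model-error term of order √(p/n) even under a perfect model). Observed:
  median mean-z within ±0.05, median SD-z within 1.01 ± a few hundredths;
  U-values from a model-drawn subject pass a Kolmogorov–Smirnov uniformity
  check (distance < 0.01 on ~12k voxels).
- Detection: a 3-SD injected effect roughly doubles the median u_0.9999^abs
  of held-out subjects (≈ 4.5 → 6.5), with every paired difference positive
  in the reported runs.

## Degenerate inputs and tie-breaks

Exactly collinear designs raise with the offending columns named (e.g. a
single-sex cohort); zero-residual data raise a degenerate-variance error;
duplicate RBF centres raise before factorisation; empty masks, empty grids
and empty cohorts raise immediately. Quantile definition throughout is
numpy's linear interpolation of order statistics. Subjects with missing
covariates are skipped (and listed) by cohort scoring, not fatal.

## Limitations

Covariates enter the mean only, linearly; no site/scanner harmonisation; no
spatial dependence model (voxelwise marginals only); the skewness bound
|γ| < 0.995 makes heavier-tailed regions fit poorly (clipped-γ voxels are
flagged); quantile estimates at the age-range boundaries extrapolate and
warn rather than fail.
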