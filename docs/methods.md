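# Methods

## Model

The response is the Neck Disability Index (integer, 0–50); the
predictors are curves observed over one time-normalized
flexion-extension cycle and, optionally, scalar summaries of those
curves. The functional linear model with scalar response is

    Yᵢ = β₀ + Σₛ ⟨xᵢ⁽ˢ⁾, βₛ⟩ + Σᵣ βᵣ⁽ᵘ⁾ uᵢᵣ + εᵢ,  εᵢ iid N(0, σ²),

with ⟨f, g⟩ = ∫₀¹ f(t)g(t) dt. Both the predictor curves and the
coefficient functions are expanded in truncated Fourier bases — the
movement is periodic, so a Fourier system represents it with few
coefficients and no boundary artifacts. Writing x(t) = Σᵣ cᵣψᵣ(t) and
β(t) = Σₛ bₛθₛ(t), the inner product becomes bᵀJc with the Gram matrix
J = [∫θₖ₁ψₖ₂ dt], so the model reduces exactly to a multiple regression
of Y on the intercept, the v-scores v = cJᵀ, and the scalar predictors.
Estimation is ordinary least squares; smoothness of β(t) is controlled
solely by the (small, odd) basis dimension K_β, not by a roughness
penalty.

### Basis convention

The basis is orthonormal on [0, 1]: {1, √2 sin(2πkt), √2 cos(2πkt)},
ordered constant, sin/cos pair per harmonic. With this scaling the
self-Gram matrix is the identity and v-scores coincide with curve
coefficients whenever K_β ≤ K_x. An unnormalized convention
{1, sin, cos, …} differs only by an invertible diagonal rescaling of
coefficients; every reconstructed function, fit statistic and predicted
value is invariant to that choice, so coefficient *vectors* from other
software are comparable only after rescaling.

### Fit statistics

For a fit with p identifiable coefficients (intercept included) on n
observations: R² = 1 − RSS/TSS, r = √R²,
F = (R²/q)/((1−R²)/(n−p)) with q = p − 1, the p-value from the upper
tail of F(q, n−p), and AIC = −2ℓ̂ + 2(p+1) where ℓ̂ is the maximized
Gaussian log-likelihood with the ML variance estimate RSS/n and the +1
counts the variance parameter. Absolute AIC values depend on this
convention; differences and rankings between models do not depend on
the additive constant. The nested-model test between fits with
p₀ ⊂ p₁ coefficients uses F = ((RSS₀−RSS₁)/(p₁−p₀))/(RSS₁/(n−p₁)).

### Aliased (structurally zero) design columns

A periodic velocity curve integrates to zero over the cycle, so its
constant Fourier coefficient is exactly zero for every observation;
depending on the phase convention of the generator a harmonic component
can vanish identically as well. The corresponding v-score columns are
identically zero and the associated bₛ are unidentifiable. As R's `lm`
does with aliased terms, such columns (norm ≤ 1e-10 of the largest
column norm) are excluded from the solve, their coefficients reported
as zero, and every degree of freedom, F statistic and AIC parameter
count is based on the effective number of identifiable coefficients.
Genuine near-collinearity among informative columns (condition number
above 1e10 after exclusion) raises an error instead, because a fit in
that regime is numerically meaningless (e.g. near-duplicate RoM/RoV
columns).

### Degenerate fits

When RSS ≤ 1e-12·TSS the fit is treated as numerically exact: r = 1,
F = ∞, p = 0, log-likelihood +∞ and AIC −∞. Without this floor,
machine-noise RSS values on noiseless data would produce arbitrary AIC
orderings among models that all interpolate the data; with it, exact
fits tie at −∞ and ties resolve toward the smaller basis. A constant
response (TSS = 0) yields R² = 0, F = 0, β₀ equal to that constant.

## Preprocessing

A continuous record is segmented at successive maxima of extension
(local minima of the flexion-positive angle) found with peak detection:
prominence at least 10% of the record's angle range and separation at
least 25% of the median inter-peak interval (a two-pass scheme — the
first pass estimates the interval). Records that begin or end at
maximum extension have boundary samples at their endpoints, which peak
detection cannot flag; endpoints whose angle sits at the level of the
detected minima are therefore accepted as boundaries. The first and
last complete cycles are discarded as warm-up/wind-down, so k detected
cycles retain k − 2. Each retained cycle is mapped affinely to [0, 1]
and linearly interpolated onto a common uniform grid of 101 points
(percent-of-cycle resolution, configurable). Angular velocity comes
from analytic differentiation of a 21-function Fourier expansion of
the angle cycle divided by that cycle's duration (deg/s); the expansion
dimension is deliberately finer than any coefficient-function basis so
curve representation is never the smoothing bottleneck. Per-cycle
velocities are averaged (each with its own duration) before the
functional mean, and RoM/RoV are max-minus-min of the mean angle and
mean velocity curves.

## Basis-dimension selection

For each candidate odd K the single-functional-predictor velocity model
is fitted and r, F, p and AIC recorded. The compromise rule makes the
usual visual judgment reproducible: among candidates with p < 0.05,
take the smallest K whose r is within 0.01 of the table maximum and
whose AIC is within 4 of the table minimum (ΔAIC ≤ 4 is the
conventional "comparable support" band); if nothing qualifies, fall
back to the AIC minimizer. An explicit `min_aic` rule is also provided.
Candidates must satisfy K < n − 2 or the fit is refused.

## Interpretation

For an observation with curve x(t), the product β̂₁(t)x(t) is evaluated
analytically from the basis representations. Its zero crossings are
bracketed on a 2001-point grid and refined by Brent bisection to 1e-10
in t; the regions between crossings tile the cycle, each region's
signed area comes from adaptive quadrature (absolute tolerance 1e-12),
and β₀ + Σ areas + scalar terms reproduces the model prediction to
better than 1e-8. Scalar-covariate contributions are reported as one
additive term, never folded into the curve regions. The number of
regions is a property of the data, not a contract. When two subjects
with similar velocity ranges but different scores are compared, the
second product curve can be rescaled by the ratio of velocity ranges so
shape differences, not amplitude, drive the per-region area
differences (integrated over the first observation's regions).

## Synthetic cohort generator

No public dataset of cyclic neck kinematics with per-observation NDI
exists, so the generator produces cohorts with the structure the
analysis assumes. Per observation: amplitude ROMᵢ ~ N(120, 15²) deg
(floored at 10), nominal cycle duration Tᵢ ~ N(2.0, 0.3²) s (floored at
0.5), three distortion harmonics k = 2..4 with relative amplitudes
dᵢₖ ~ N(0, 0.05²) and uniform phases. The within-cycle angle is

    s(τ) = (ROMᵢ/2)[−cos 2πτ + Σₖ dᵢₖ sin(2πkτ + φᵢₖ)],

i.e. a fundamental starting at maximum extension plus an individual
shape signature. Records repeat this cycle 7 times at 100 Hz with 2%
relative per-cycle duration jitter and 0.5 deg measurement noise.
Responses follow the functional linear model with the *noiseless*
analytic velocity curve: NDIᵢ = round(clip(β₀ + ∫β₁ωᵢ dt + εᵢ, 0, 50)),
β₀ = 14.95, εᵢ ~ N(0, 6²). Because ωᵢ and β₁ both live in the K = 9
orthonormal span, the integral is an exact dot product, giving exact
ground truth. The default β₁ weights the distortion harmonics
(0.25 on the second, 0.10 on the third, per sine and cosine), so the
signal lives in movement *shape* rather than amplitude — RoV then
correlates only weakly with the score while the functional model
captures it, reproducing the qualitative contrast the method is built
to exhibit; the response noise of 6 points puts the velocity model's
multiple correlation in the 0.6–0.7 regime typical for this kind of
cohort. All observation-level draws precede record sampling, so
curves-only and full-record generation give identical responses for a
seed, and everything is bit-reproducible from the single seed.

What the generator does **not** emulate: marker-level measurement
physics, within-subject before/after treatment structure (sessions are
independent draws), asymmetric flexion/extension phases, fatigue drift
across cycles, or non-Gaussian score noise. Passing tests therefore
demonstrate correctness of the statistical machinery under the model's
own assumptions, not robustness to every feature of clinical data.

Ground-truth versus preprocessed curves: segmentation anchors cycles at
the minimum of the *distorted* angle shape, a small circular phase
offset from the generator's nominal cycle start, so preprocessed curves
match the analytic ones up to that registration (≈2% of range after
alignment). Exact-recovery and calibration studies consequently fit on
the analytic curves; the full-record path is validated separately for
shape and amplitude agreement.

## Study sizes in the validation suite

The simulation studies use the cohort sizes natural to the design:
n = 55 single-session observations for calibration (2000 null
replicates; rejection rate checked against the 0.04–0.06 band and
p-value uniformity by Kolmogorov–Smirnov), n = 60 for noiseless
recovery, 20 cohorts for the reduction-equivalence check, 100
observations for decomposition conservation, and 100 replicates at
n = 50 and n = 400 for the RMISE-scaling study.

## Known limitations

- Responses are conditionally Gaussian and homoscedastic; the bounded
  integer nature of the NDI is only respected by rounding/clipping in
  the generator, not by the fitting model (consistent with standard
  practice for this instrument).
- The two sessions of a subject are treated as independent
  observations; no within-subject random effect is modeled.
- Only the first derivative of basis curves is implemented; higher
  derivatives (accelerations) are out of scope.
- Segmentation assumes flexion-positive angles with cycle boundaries at
  extension maxima; other sign conventions require negating the input.
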