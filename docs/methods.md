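# Methods

## Model

State `X(t) = (C(t), N(t))`, diabetics with complications and all diabetics;
`D = N − C` is derived.  The dynamics are the Itô SDE

    dC = [−(λ(t)+θ(t)) C + λ(t) N] dt + g₁(t) dW
    dN = [I(t) − (ν+δ)(t) C − μ(t) N] dt + g₂(t) dW

with one scalar Wiener process `W` driving both components, rates
`rate(t) = slope·t` (years since the calibration baseline), and additive
noise `g₁ = K₃ sin t`, `g₂ = K₃ cos t` whose vector norm is constantly `K₃`.
θ = γ+μ+ν+δ is the combined removal rate; γ (complication repair) never
appears on its own and has no separate representation.

Writing the drift as `b(x,t) = A(t)x + (0, I(t))` gives `A(t) = t·M` with

    M = [[−(λ̇+θ̇), λ̇], [−(ν+δ)̇, −μ̇]]

(dots denote slopes).  For the canonical slopes
(0.02, 0.01, 0.05, 0.007, 0.002 per year²) M is Hurwitz, eigenvalues
≈ −0.00852 and −0.02348, and the unique equilibrium solving
`M x* = −(0, İ)` is `(C*, N*) = (5, 7.5)`.

Since the family `A(t) = t·M` commutes with its integral, the zero-noise
flow has the exact form

    x(t) = exp(M t²/2) (x₀ − x*) + x*,

implemented via `scipy.linalg.expm` and cross-checked against an adaptive
ODE solve at 1e-8.  Because the drift is affine and the noise additive,
this same expression is the exact mean of the stochastic solution, and the
difference of two solutions driven by the *same* noise is fully
deterministic: `e(t) = exp(M(t²−s²)/2) e(s)`.  Both facts are used as
oracles throughout the tests.

## Hypothesis bounds and the Lipschitz constant

Existence/uniqueness-style conditions are checked on a user-declared finite
horizon: `J = sup_{[0,T]} max(θ(t), λ(t)) = T·max(θ̇, λ̇)` for linear rates,
`K₂ = K₃` (the envelope of `(g₁, g₂)` is exact), and `L = √7·J`.  The √7
comes from bounding the coefficient-matrix norm by the root of the sum of
its squared entries, each at most J² (seven J² in total after expanding
(λ+θ)² ≤ 4J²); a rendering of this constant without the square root
circulates, but the derivation forces √7·J and that is what we implement.
Two conditions can never hold globally and are *reported*, not enforced:

- linear-growing λ, θ are unbounded on all of ℝ⁺ (`global_boundedness`
  violation whenever a slope is positive);
- the conventional starting pair (C₀, N₀) = (0.65, 0.10) has N₀ < C₀,
  i.e. D₀ < 0 (`initial_ordering`).  Units of C and N are nowhere fixed by
  the data source; we treat them as dimensionless.

Trajectories likewise count (never clip) negative components and ordering
violations: additive Gaussian noise does not preserve positivity.

## Calibration

Each rate series is fitted through the origin (`slope = Σ t·y / Σ t²`)
because the model has no constant terms; `t = year − baseline` with
baseline 2011 for the packaged 2012–2016 table, chosen because it
reproduces the canonical λ and I slopes at two decimals (λ: 0.0200945…,
θ: 0.0103, I: 0.0498).  The ν+δ and μ columns of the packaged table are
*not* reproducible as 0.007 and 0.002 by any simple fit we tried
(through-origin LS gives 0.00179 and 0.00042; neither a mean of y/t nor a
fit over calendar years helps).  We therefore ship the canonical values as
simulation defaults (`DiabetesSDE.canonical()`, `ModelParams()` defaults)
and report fitted values separately; nothing in the package silently mixes
the two.  No intercept, no uncertainty intervals, no smoothing — parameter
uncertainty is probed only through the synthetic-fixture Monte-Carlo below.

## Synthetic surveillance tables

`generate_fixture(slopes, n_years, noise_sd, seed)` emulates a yearly
surveillance table: `rate = slope·t + N(0, noise_sd)`, truncated at zero so
the table stays valid.  Defaults follow the packaged table's shape
(5 years); `noise_sd = 0.001` in tests is of the order of the packaged
table's residuals around the linear fit.  The generator emulates *only*
independent Gaussian scatter around an exactly linear trend — no serial
correlation, no reporting artefacts, no shared sampling error across
columns — so a green parameter-recovery test establishes unbiasedness of
the through-origin estimator under that stated world, not robustness to
real surveillance pathologies.  Truncation bias is negligible at the
default noise level (≲2e-7 on the smallest slope) and is deliberately not
corrected.

## Numerical schemes

Euler–Maruyama: `X_{k+1} = X_k + b(X_k,t_k)Δt + B(t_k)ΔW_k`.  Milstein adds
`½ B (∂B/∂X)(ΔW² − Δt)`; the diffusion here is state-independent, so the
correction is identically zero and Milstein ≡ EM **bitwise** — asserted in
tests rather than re-implemented.  A `dB_dx` hook exists so the correction
arithmetic itself is exercised with a non-zero derivative.

Blow-up policy: a non-finite state aborts integration with the step index
(long horizons with t-growing coefficients are stiffness-prone for explicit
schemes); NaNs never propagate silently.

A vectorised ensemble driver orders its per-step arithmetic identically to
the scalar loop, and a test pins bitwise agreement between the two, so the
fast path cannot drift into being a second model.

## Brownian machinery

Meshes derive their step count from the endpoints (`n = (T−t₀)/dt`, exact
tiling required); a printed convention of "N+1 = 501 points for T = 500,
Δt = 0.01" is internally inconsistent (it implies 50 000 steps) and is
ignored in favour of the derived count.  Increments are i.i.d. N(0, Δt)
from one named `numpy` generator per path.  Negative times use the
reflection `W(−t) = −W(t)` — the customary construction for pullback
experiments; it is *not* an independent two-sided Wiener process (the two
sides are perfectly anticorrelated), which is harmless here because every
pullback/coalescence statistic is a same-path difference from which the
noise cancels exactly.  An `independent` mode provides the statistically
correct two-sided construction for anyone who needs it.  Dyadic coarsening
keeps shared-grid values bit-identical to the fine path, so all levels of a
convergence study are coupled to one realization.

## Convergence-order estimation

Strong error is the RMS over paths of the terminal-state error (pointwise
at T, not sup over time).  Reference = the finest-level run on the shared
path (standard practice; no closed-form stochastic solution is used).
Order = least-squares slope of log error vs log Δt; levels with error below
1e-12 are excluded with a warning (they arise only in the fully frozen
zero-drift, zero-noise model).  Defaults (finest 2⁻¹², factors 2/4/8,
200 paths, seed 42) finish in seconds on one CPU.

Two numerical caveats, both documented because they are easy to misread:

- With the reference only a factor 2 below the first level, an order-1
  scheme's errors scale like `Δt − Δt_finest`, biasing the fitted slope up
  to ~1.3–1.4.  The guaranteed-order claim (≥ 0.5) is unaffected.  For the
  noise-free model a `reference="exact"` option compares against the closed
  form instead and recovers slope 1.00.
- EM integrates additive noise exactly only when B is *constant*; with the
  time-varying `B(t) = (K₃ sin t, K₃ cos t)` the left-endpoint rule leaves
  an O(Δt) noise-quadrature error even at zero drift.

## Pullback stability probe

`pullback_experiment` fixes the observation time t, starts two states at
`t − τ` for increasing lags τ on the same (reflected where needed) path,
and records the difference norm at t next to the oracle
`‖exp(M(t²−s²)/2)Δx₀‖`.  Agreement is within a 10·Δt budget.  Note the
decay factor from s = 0 to t = 40 is `exp(−0.00852·800) ≈ 1.11e-3` — close
to, but above, 1e-3; and for start times before t = 0 the factor `t` in
`A(t) = t·M` flips sign, so differences *grow* on the negative-time
segment, exactly as the oracle predicts.  Noise cancellation in these
differences is exact in real arithmetic; floating point leaves a ~1e-14
residue, so seed-independence is asserted at atol 1e-12 rather than
bitwise.

## Defaults

| parameter | default | why |
|---|---|---|
| slopes λ̇, θ̇, İ, (ν+δ)̇, μ̇ | 0.02, 0.01, 0.05, 0.007, 0.002 /yr² | canonical reference calibration |
| K₃ | 5.0 | reference noise amplitude |
| x₀ | (0.65, 0.10) | conventional starting pair (kept despite N₀ < C₀) |
| Δt | 0.01 yr | reference mesh |
| MC sizes | 200 paths (order), 2000 (mean check) | minutes on one CPU |
| seeds | explicit everywhere, default 42 | reproducibility |

## Known limitations

- No microscopic (insulin–glucose) dynamics; this is a surveillance-scale
  compartment model.
- Theoretical Gronwall constants behind the stability/convergence theorems
  are not computed; the claims are verified empirically.
- No weak-convergence machinery, no higher-order or adaptive schemes, no
  Lévy areas (single scalar driver).
- Calibration assumes exact linearity in t; it does not model the sampling
  process behind the surveillance rates.
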