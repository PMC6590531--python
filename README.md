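# diabsde

Stochastic modelling of diabetes prevalence with complications, for
epidemiologists and applied-SDE numericists who want a small, fully seeded,
testable simulator rather than a figure-generating script.

## The model

The state is `X(t) = (C(t), N(t))`: the number of diabetics with
complications and the total number of diabetics in a surveillance region
(`D = N − C` are the complication-free diabetics).  Yearly surveillance data
suggest epidemiological rates that grow roughly linearly in time,
`rate(t) = slope · t` with `t` in years since a baseline.  With a single
scalar Brownian driver `W` and additive periodic noise, the model is the
two-dimensional Itô SDE

    dC = [ −(λ(t) + θ(t)) C + λ(t) N ] dt + K₃ sin(t) dW
    dN = [ I(t) − (ν(t)+δ(t)) C − μ(t) N ] dt + K₃ cos(t) dW

where λ is the complication rate, θ = γ+μ+ν+δ the combined removal rate,
I the incidence, ν+δ the severe-disability-plus-complication-mortality rate
and μ background mortality.  The drift is affine, `b(x,t) = A(t)x + (0, I(t))`
with `A(t) = t·M` for a constant Hurwitz matrix `M`, which gives a
closed-form zero-noise solution `x(t) = exp(M t²/2)(x₀ − x*) + x*` that also
equals the exact mean of the stochastic solution.  The package provides:

- **calibration** — through-origin least squares `slope = Σ t·y / Σ t²`
  per rate series from a yearly CSV table (a Fujian-province 2012–2016 table
  is packaged), plus synthetic fixture tables with known ground truth;
- **brownian** — seeded Wiener paths on uniform meshes, reflection through
  time zero for pullback runs, and dyadic coarsening that keeps all levels
  coupled to one noise realization;
- **schemes** — Euler–Maruyama and Milstein one-step integrators (they
  coincide bitwise here: the Milstein correction vanishes for additive
  noise) and the closed-form deterministic oracle;
- **diagnostics** — strong (mean-square) convergence-order estimation on
  coupled paths, pullback mean-square stability probes checked against the
  matrix-exponential difference oracle, trajectory coalescence, ensemble
  summaries.

## Worked example

```python
import diabsde

model = diabsde.DiabetesSDE()       # packaged Fujian 2012-2016 table
res = model.fit()
print(res.summary())
```

```
Stochastic diabetes-complication model (2-D linear SDE)
==========================================================
rate          slope [1/yr^2]           RSS   canonical
----------------------------------------------------------
lambda               0.02009     4.418e-06       0.020
theta                0.01031     1.788e-04       0.010
incidence            0.04983     1.069e-04       0.050
nu_delta             0.00179     2.506e-05       0.007
mu                   0.00042     2.253e-06       0.002
----------------------------------------------------------
noise amplitude K3 = 5   x0 = (0.65, 0.1)
equilibrium (C*, N*) = (20.5121, 31.0409)
eigenvalues of M: -0.02916, -0.00167  (mean-square stable)
warning: global_boundedness: lambda(t), theta(t) grow linearly and ...
warning: initial_ordering: N0=0.1 < C0=0.65 implies D0 < 0
```

The λ, θ and I slopes reproduce the canonical reference values 0.02, 0.01,
0.05 at two decimals; the ν+δ and μ columns do not (0.00179 and 0.00042
versus the canonical 0.007 and 0.002), so the canonical values ship as
simulation defaults (`DiabetesSDE.canonical()`) and the fitted ones are
reported alongside — see `docs/methods.md`.  Both warnings are expected:
linearly growing rates cannot be globally bounded, and the conventional
starting pair (0.65, 0.10) has N₀ < C₀.

Diagnostics hang off the results object:

```python
res = diabsde.DiabetesSDE.canonical()
conv = res.convergence_study(n_paths=200, seed=1)
print(conv.rms_errors, round(conv.fitted_order, 3))
# [0.00163 0.00464 0.01026] 1.327   -> strong order ~1 >= 0.5

st = res.pullback((0.70, 0.10), (0.65, 0.11), t_fixed=40.0, taus=[10, 20, 40], seed=1)
print(st.diffs)   # [2.586e-03 3.093e-04 5.633e-05]
print(st.oracle)  # [2.596e-03 3.112e-04 5.667e-05]
```

The pullback differences decay monotonically in the lag τ and track the
noise-free matrix-exponential oracle `‖exp(M(t²−s²)/2)Δx₀‖` to within the
discretization budget: two solutions driven by identical noise coalesce —
the empirical face of mean-square asymptotic stability.

A `diabsde` console script wraps the same operations
(`diabsde simulate|calibrate|convergence|stability|fixtures --help`).

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch, the fitted strong
convergence order of the Euler–Maruyama scheme on the canonical model
(horizon [0, 5], finest step 2⁻¹², 200 Brownian paths coarsened by factors
2/4/8 with the finest run as reference) and writes it as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
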