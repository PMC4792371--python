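# Methods

## The constitutive model

A blood clot forming between the plates of a rheometer is modeled as an
incompressible, homogeneous viscoelastic material under simple shear.  The
mechanical skeleton is a generalized Maxwell model: an equilibrium
Neo-Hookean spring (modulus `G00`), an equilibrium dashpot (viscosity
`eta00`, in parallel with the plasma viscosity `eta_p`), and two Maxwell
modes `(G10, eta10)`, `(G20, eta20)` — two modes suffice to describe the
frequency window probed experimentally (0.63–63 rad/s).  The extra stress
is

    tau = tau_v + tau_e + tau_ve_1 + tau_ve_2

    tau_v    = 2 (eta_p + f_v(t) f_vi(I_B) eta00) D
    tau_e    = f_e(t) x0 f_ss(I_B) G00 (B - I)
    tau_ve_i = x_i f_e(t) G_i0 (B_e,i - I)

with `B` the Finger tensor of the imposed deformation and `B_e,i` the
elastic Finger tensor of mode i.  No hydrostatic pressure term is carried:
only the shear component is compared to data.

Four phenomenological ingredients extend the linear skeleton:

* **Formation kinetics.**  Clotting converts the sample from a nearly
  Newtonian fluid into a viscoelastic solid.  The clot viscosities scale
  with `f_v(t) = 1 - exp(-(t - t0)/tc)` (zero before the delay time `t0`)
  and the moduli with `f_e = f_v^2`.  The quadratic relation makes the
  elastic stress rise more slowly at first, producing the experimentally
  observed monotone decrease of the loss angle `delta = arctan(G''/G')`
  after `t0` — the fluid-to-solid transition.
* **Softening.**  Large deformation cycles irreversibly reduce the
  stiffness (a Mullins-like effect).  Each modulus carries a state
  parameter `x_i ∈ (0, 1]` that relaxes toward
  `x_inf = exp(-a sqrt(I_Be,i - 3))` at rate `cx` whenever `x_i > x_inf`
  and never increases.  Each mode softens at its own pace because each has
  its own elastic Finger tensor.
* **Strain stiffening.**  The equilibrium modulus grows with strain as
  `f_ss = (1 + k1 (I_B - 3))^n1`; `I_B - 3 = gamma^2` in simple shear, so
  the factor is symmetric in strain and equals one at rest.
* **Nonlinear viscous dissipation.**  The equilibrium-dashpot viscosity
  grows as `f_vi = 1 + k2 (I_B - 3)`.

### Inelastic flow rule

Each Maxwell mode evolves its inelastic right Cauchy–Green tensor
`C_p = F_p^T F_p = F^T B_e^{-1} F`.  Differentiating that identity with a
symmetric (spin-free) inelastic velocity gradient gives

    dC_p/dt = C_p F^{-1} D_p F + (C_p F^{-1} D_p F)^T,
    D_p,i   = tau_ve,i / (2 eta_i)

Note the symmetric pair: the single term `C_p F^{-1} D_p F` alone (a form
that appears in parts of the literature without its transpose) yields a
mode that relaxes with time constant `2 eta/G` and a loss modulus ~12% off
the closed-form spectrum at `lambda*omega ≈ 2*pi`.  The pair restores
`lambda = eta/G` and reduces to the familiar `2 F^T D_p F` small-elastic-
strain form.  The package's linear-regime oracle test pins this down to
better than 0.1%.

During formation `eta_i(t) = f_v eta_i0` enters the flow rule; before
`t0` the modes carry no stress and `D_p,i` is defined as zero (avoiding
0/0).  Softening applies to moduli exactly once (`x_i G_i0`); `eta00` is
modulated by `f_vi` but by no state parameter.

## Numerics

Time integration is fixed-step classical RK4 on the two `C_p` tensors,
specialized to simple shear (`F = I + gamma e_12`, analytic inverse),
compiled with numba.  The step satisfies both `dt <= T/200` per
oscillation period and `dt <= lambda_min/20` (defaults; the fitting loops
use T/100 and lambda_min/10, which changes extracted features by well
under 0.1%).  After each step `C_p` is symmetrized to remove round-off
drift; positive definiteness is monitored and a failed state raises with
the last valid time.  The softening states are advanced by operator
splitting with the exact exponential solution of the linear relaxation
ODE (unconditionally stable, and the basis of the 1e-6 agreement with the
closed form asserted in the tests).  Initial conditions are the virgin
state `C_p = I`, `x = 1` (stress-free start).  Oscillatory phases use a
sample rate snapped to an integer number of samples per period so phases
spanning whole periods end exactly at strain zero — otherwise a small DC
strain leaks into subsequent phases and visibly distorts the
smallest-amplitude steps.

Degenerate Maxwell modes (zero modulus or viscosity) contribute zero
stress and are skipped.  The protocol grammar includes a constant-rate
("steady") phase kind alongside oscillations, used to exercise the model
against the start-up-of-shear closed form.

## Synthetic data: what it emulates and what it does not

No rheometry data accompany the model, so the package generates its own:
the standard three-part protocol (formation at 1 Hz, amplitude 0.01, 30
min; frequency sweep 0.63–63 rad/s at amplitude 0.01, ten log-spaced
frequencies held for ten cycles each; LAOS ladder 0.01 → 1 in 11
logarithmic steps at 1 Hz, 30 s per step, then one final 0.01 step),
simulated in one continuous run with state carried across phases.  The
formation and sweep phases are reduced to moduli by harmonic projection
(least-squares sin/cos fit referenced to the strain's own phase), the way
a rheometer readout would; the LAOS phase stays a raw
(time, strain, stress) trace at 100 samples per cycle.  Noise is
multiplicative Gaussian on the stress (default 2% SD) plus an optional
additive floor; strain is treated as exactly imposed.

The ground-truth parameter set describes a whole-blood-like clot and was
chosen once on rheological grounds: solid-like response with G' an order
of magnitude above G'' across the sweep; Maxwell viscosities (40 and
2 Pa·s; relaxation times 1 s and 0.1 s) far above the equilibrium-dashpot
viscosity (0.5 Pa·s); a formation delay of 2 min with a 5-min time
constant so the moduli plateau within the 30-min window; softening that
is visible but levels off within a 30 s amplitude step
(`a = 1, cx = 0.05 1/s`); and clear stiffening and dissipation
nonlinearity at amplitude 1 (`k1 = 2, n1 = 1, k2 = 2`).

What passing round-trip tests on these data do **not** show: robustness
to instrument artifacts (tool inertia, compliance, wall slip, drying),
to drift or non-Gaussian noise, to inter-individual biological
variability, or to model misspecification — the generator and the fitted
model share the same equations by construction.  They do show that the
estimation pipeline is consistent and that every parameter is
identifiable from the protocol at realistic noise.

## The stepwise fit

1. **Linear spectrum.**  `G00, G10, G20, eta00, eta10, eta20` by bounded
   trust-region-reflective least squares on relative residuals of
   (G', G'') over the sweep; `eta_p` fixed at 4 mPa·s; multi-start (5
   perturbed initializations) against local minima; modes reported in
   order of decreasing relaxation time.
2. **Formation.**  `(t0, tc)` by joint least squares on the formation
   moduli curve, each channel normalized by its maximum so the much
   larger G' does not dominate; `t0` bounded above by the first sample
   exceeding 5× the noise floor (regularizing the non-smooth switch).
3. **Nonlinear stage.**  Per-amplitude-step Lissajous features feed an
   alternating loop: with `(a, cx)` fixed, one simulation provides the
   per-cycle softening states and Maxwell peak stresses, making the
   peak-stress residual a closed form in `(k1, n1)` (the
   stiffening-extraction balance rearranged); with `(k1, n1)` fixed,
   `(a, cx)` are refit by full simulations.  Both half-steps minimize the
   same residual, so the loop is a true block-coordinate descent and its
   objective decreases monotonically (asserted in the tests).  Iteration
   stops when the largest relative parameter change falls below 0.01.
   `k2` is fitted last, against the rising-branch stresses at
   `gamma0/2` and `(sqrt2/2) gamma0` and the per-cycle loop widths at
   those strains.

Numerical choices that mattered, each a deliberate design decision:

* **Per-cycle rather than per-step residuals.**  The last-cycle peak
  stresses alone cannot separate `a` from `cx` (a large-`a`/small-`cx`
  pair mimics the equilibria); the per-cycle peak-stress and
  minimal-strain-modulus series resolve the within-step kinetics and
  restore identifiability.
* **Pre-softening correction.**  The sweep measures the moduli of a clot
  already softened by its small-amplitude history, `G~_i = x_pre,i G_i0`
  with `x_pre,i = exp(-a gamma_e,i)` at amplitude 0.01 (viscosities are
  measured unbiased because a mode's apparent relaxation time is
  `eta_i/(x_i G_i)`).  The nonlinear stage divides this factor out for
  the current candidate `a` and starts its simulations from `x = x_pre`,
  which keeps the stages mutually consistent and also returns the true
  mature moduli.  Without it every stress is ~1% off and the optimizer
  buys back that bias with 20–30% parameter distortions.
* **Joint polish.**  The alternating loop zigzags slowly along the
  coupled softening/stiffening valley; once it satisfies its 0.01
  stopping rule, a joint trust-region refinement of `(a, cx, k1, n1)` on
  the same residual removes the remaining coupling bias.  The polish is
  accepted only if it does not increase the objective.
* **Width estimator.**  Loop widths from two-point interpolation are too
  noisy to pin `k2` (the viscous stress is a small fraction of the
  total); stresses at the target strains are instead estimated by local
  linear regression over a ±0.15·gamma0 strain window per branch, and
  the signed rising-minus-falling difference is used (an absolute value
  would fold zero-mean noise wherever it exceeds the width, biasing `k2`
  upward).
* **Initial softening guess.**  `a` from the softening level reached at
  the largest amplitude, `-ln(Gm_end/Gm(0))/gamma0_max`; `cx` from the
  geometric within-step decay of `G_m` during that step (while
  `x > x_inf` the state relaxes at exactly `cx`).  Starting values only.

Fit quality is the mean relative stress error
`zeta = (1/N) sum |tau_exp - tau_model| / |tau_model|` over the LAOS
trace; samples where `|tau_model|` falls below 1e-3 of its maximum are
excluded (the raw stress crosses zero twice per cycle, where a relative
error is undefined).  `zeta` is scale-invariant.

Typical results at the default conditions: noise-free round trips recover
all thirteen parameters within ~1% with `zeta ≈ 3e-4`; at 2% stress noise
the weakly identified trio `eta00, cx, n1` scatters most (the first
because the equilibrium dashpot contributes little to G'' below the
Maxwell modes, the last two through the softening/stiffening coupling).

## Sensitivity analysis

Three scalar outputs summarize the nonlinear features over the
amplitude-1 interval: the relative drop of the peak stress (O_so, for
softening), the maximum stress normalized by `G00` (O_ss, stiffening),
and the width of the interval's first Lissajous cycle at
`(sqrt2/2) gamma0` (O_vi, dissipation — the first cycle, where softening
has barely acted).

Main and total Sobol indices of `(a, cx, k1, n1, k2)` come from a
generalized polynomial chaos surrogate: uniform ranges (±50% around the
default set; exposed in the CLI), scrambled Sobol-sequence sampling,
total-degree-3 expansion in orthonormal shifted Legendre polynomials
fitted by least squares on 280 runs — five times the 56 basis terms, the
arithmetic that fixes the degree at 3.  Indices follow analytically from
the squared coefficients.  A Saltelli pick-and-freeze Monte Carlo
estimator (Saltelli-2010 main with a centered product, Jansen total) is
the independent cross-check; it is the test oracle, never the
implementation.  Output variances indistinguishable from zero (relative
to the squared mean response) short-circuit to all-zero indices.

On the default ranges the analysis reproduces the expected structure:
`a` and `cx` carry ~99% of O_so's main-index mass; O_ss is led by
`n1` and `k1` with a side contribution from `a`; `k2` has the largest
single main index for O_vi with the stiffening pair contributing through
the softened-stress asymmetry.

## Known limitations

* `simulate()` integrates simple-shear protocols only (the tensor
  operations accept arbitrary deformations, but no general-deformation
  driver is provided).
* The mode count is fixed at two Maxwell modes.
* `k2` and `cx` are intrinsically weakly identified from a single
  protocol at 2% noise (medians land near 8%); widening the amplitude
  ladder or averaging replicates is the remedy, not tighter optimizer
  settings.
* The Monte Carlo cross-check of the clot-model indices uses a shortened
  amplitude ladder (4 steps, 15 s each) to keep its ~10^4 simulations
  affordable; both methods see the identical model, so the comparison is
  unaffected.
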