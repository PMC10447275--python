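# Methods

## Model structure and assumptions

The eye is represented by five well-mixed compartments — tears,
sclera–choroid, retina, vitreous humor and aqueous humor — exchanging
drug through the routes sketched in the README. The main physical
assumptions are:

- **Well-mixed tissues.** Concentration in each tissue is independent
  of position; spatial gradients exist only across the lens.
- **Lumped sclera–choroid.** No significant transport barrier separates
  sclera from choroid, so they share one compartment and one partition
  coefficient.
- **Negligible endothelial resistance.** The corneal stroma is lumped
  with the aqueous humor; the epithelium is kept as a separate,
  purely diagnostic equilibrium compartment (it stores negligible mass
  and feeds nothing back into the balances).
- **Homogeneous slab lens.** Thickness H is uniform; transport in the
  lens is 1-D transverse diffusion with constant D_SCL. The post-lens
  tear film volume is neglected: the back face exchanges directly with
  the aqueous humor through the corneal permeability P_t-Aq.
- **Linear, passive transport.** All exchanges are linear in
  concentration — no active transport, metabolism, or binding
  saturation. Consequently the whole system is linear in the source
  strength, which the tests exploit (doubling the dose doubles every
  concentration).
- **Unit tissue density.** Concentrations per gram (ng/g) and per mL
  are interconverted assuming 1 g/mL for every tissue.

The lens boundary conditions need one interpretation decision. As
written, the back-face condition equates a flux density to a total rate
(the right side contains A_Cornea). The only dimensionally consistent
reading that conserves drug is to treat both boundary exchanges as
**total rates**: `(−D_SCL ∂C/∂y|_H)·A_SCL = A_Cornea·P_t-Aq·(C(H)/K_SCL − C_Aq)`,
so the mass leaving the back of the lens is exactly the mass crossing
the cornea. The front-face rate is signed so that a lens richer than
tears equilibrium delivers a positive rate to the tears; conservation,
not typesetting, fixes the convention.

### Two source modes

- **diffusion** — the lens PDE is discretized (below) and coupled to
  the compartments through its two boundary fluxes. Initial condition:
  uniform loading C0_SCL, all tissues at zero.
- **release** — for devices whose release is not purely diffusive, the
  measured cumulative in-vitro release `f(t) = M_Released(1 − e^{−t/T})`
  replaces the slab. The release rate R(t) = (M_Released/T)e^{−t/T} is
  split: F·R into the aqueous humor, (1−F)·R into the tears, where F is
  the aqueous bioavailability fitted from in-vivo data. In this mode the
  lens symbols (D_SCL, K_SCL, H) are inert, which the tests assert.

## Parameters, units and provenance

Everything is stored in one internal unit system {cm, mL, s, ng};
inputs carry unit tags ("4.2 uL/min") and are converted exactly once.
The `rabbit_dexamethasone()` preset bundles the literature rabbit
anatomy (V_t = 7e-3, V_ScCh = 0.361, V_Ret = 0.086, V_Aq = 0.325,
V_Vit = 1.7 mL; A_Globe = 8.6, A_Palp = 14, A_Bulb = 3 cm²), physiology
(Q_UvSc = 0.176, Q_Vit-Aq = 0.19, Q_Aq = 4.2, Q_Drain = 0.5 µl/min;
Clearance_ScCh = 1 mL/min) and dexamethasone barrier properties
(P_Conj = 2.5e-6 cm/s, P_ScCh-Ret = 1e-5 cm/s, K_ScCh = 15, K_Ret = 10,
F = 2.08%). The inner-limiting-membrane permeability is derived, not
independent: P_Ret-Vit = 1.3 × P_ScCh-Ret = 1.3e-5 cm/s (the ILM is a
weaker barrier than the retinal pigment epithelium).

Several quantities have **no published rabbit value** and are explicit
working choices, flagged as such in the code:

- A_Cornea = 2.0 cm² and A_SCL = 2.27 cm² (required by the corneal and
  lens exchange terms).
- The preset release curve, M_Released = 2.0e5 ng and T = 2 days:
  representative of a weekly dexamethasone-eluting lens delivering
  ~200 µg, giving aqueous peaks of a few hundred ng/mL. Scaling
  M_Released rescales every output exactly (linearity).
- The diffusion-mode demo lens (H = 100 µm, D_SCL = 1e-9 cm²/s,
  K_SCL = 20, P_t-Aq = 1e-5 cm/s — inside the 2–25e-6 cm/s span
  reported ex vivo for dexamethasone across the cornea).
- K_Ep/Aq and K_Ep/t have no reported values; they default to `None`
  and the epithelium series is then emitted as missing rather than
  silently zero.

F is stored internally as a fraction in [0,1] and rendered as percent
only at the I/O boundary, eliminating a 100× error class.
`validate()` distinguishes fatal violations (signs, missing mode
requirements) from physiological warnings (e.g. Q_UvSc > Q_Aq).

## Numerics

**Discretization.** Uniform grid of n_nodes (default 50) across the
lens; second-order central differences inside. The y = 0 node is
algebraically slaved to K_SCL·C_t (integrating it would introduce an
artificial stiff relaxation constant), and the y = H node enforces the
flux condition through a second-order ghost node.

**Exact discrete conservation.** The quantity the semi-discrete scheme
transports through the anterior face is the conservation-law face flux
`D_SCL·A_SCL·(C1 − C0)/dy`; the tears balance receives exactly that,
and the anterior half-cell — which is slaved to tears equilibrium —
is carried as an additional tears capacitance
`V_t_eff = V_t + A_SCL·K_SCL·dy/2`. With this bookkeeping,
lens + compartments + sinks is a *linear invariant* of the ODE system
and is conserved to machine precision by the integrator (linear
invariants are preserved exactly by linear multistep methods). The
public `front_flux` diagnostic uses the one-sided second-order gradient
and agrees with the transported flux to O(dy²). Without this treatment
the unresolved boundary layer at t → 0⁺ loses ~dy/(2H) ≈ 1% of the
load at the default grid, which would swamp the 0.1% audit target.

**Verification.** Against the classical Fourier-series solution for a
slab with both faces clamped to zero and uniform initial load, the
n = 50 solution is accurate to ~8e-6 (relative, at t = 0.1·H²/D), and
the error falls ×4 per grid doubling (measured order ≈ 2.05).

**Stiff integration.** V_t = 7e-3 mL against ~5e-5 mL/s of tears
losses gives a time constant of minutes, versus a 7-day horizon —
a stiffness ratio of ~10³–10⁴. The integrator is BDF (`solve_ivp`)
with rel_tol = 1e-8, abs_tol = 1e-12 and the **exact constant
Jacobian**: because the model is linear, the matrix A of y' = Ay +
R(t)·b is assembled once by evaluating the right-hand side on the
canonical basis. Default output grid: 600 s steps over 604800 s
(7 days), matching the span of week-long lens studies.

**Sink bookkeeping.** Five cumulative accumulators are integrated
alongside the state: tear drainage, palpebral conjunctiva, uveoscleral
seepage into the orbit, choroidal clearance, and aqueous renovation.
Q_Aq is *total* aqueous turnover and already contains the uveoscleral
fraction that re-enters the sclera–choroid, so the renovation sink logs
(Q_Aq − Q_UvSc)·C_Aq and nothing is double-counted. The audit
`|stored + removed − delivered|/delivered` stays below 1e-8 (release
mode) and machine precision (diffusion mode) over the full week.

## Release fitting and bioavailability

The exponential release model is fitted by unweighted nonlinear least
squares **on the cumulative curve** (numerically differentiating data
to fit the rate would amplify noise). The starting point is
deterministic and scale-free: M₀ = max(cumulative), T₀ = the time the
curve crosses 63.2% of M₀ by linear interpolation — so the fit is a
pure function of the data. Whether to weight residuals or drop the
t = 0 point was an open choice; unweighted least squares over all
points is used.

Bioavailability uses the closed form of the fitted mono-exponential:
AUC = C0·τ (the integral extrapolated to zero concentration), then
F = Q_Aq·AUC/M_Released. Fitting the simulated fixture's aqueous curve
sampled at 7 realistic study times recovers the input F = 2.08% as
~2.15% (+3.5%); the gap is the mono-exponential approximation of a
curve that rises over the first hours, and is covered by the 5%
closed-loop tolerance.

## Sensitivity analysis and uncertainty propagation

One-at-a-time analysis scales each parameter by (1 ± 10%), re-simulates
and reports Δmetric(%)/|Δparameter(%)| for AUC and Cmax per
compartment. The two directions are reported as separate rows
(symmetrizing would lose curvature information). The default parameter
list covers the physiological flows/clearance and the drug barrier
properties and partition coefficients, plus F in release mode;
anatomical quantities are held constant, and M_Released/T are excluded
by default (they are the measured release curve, not a tissue or
transport property) but can be passed explicitly — the AUC coefficient
of M_Released is exactly 1.0 and serves as a linearity check. AUC here
is integrated over the simulated horizon, not extrapolated to infinity.

With the rabbit/dexamethasone values this analysis ranks choroidal
clearance (coefficient ≈ −0.9 for the posterior tissues), the tears
partition coefficient K_t (≈ −0.8, through the bulbar driving force
C_t/K_t), and the destination partition coefficients K_ScCh/K_Ret
(≈ ±0.9–1.0 for retina and vitreous) as the strongest AUC levers;
conjunctival permeability carries ≈ +0.15 for the inner tissues because
its delivery role (bulbar, A_Bulb = 3 cm²) is largely offset by its
drain role (palpebral, A_Palp = 14 cm²). K_ScCh barely affects the
sclera–choroid's own AUC since choroidal clearance, which carries no
partition factor, dominates every K-scaled outflow by two orders of
magnitude. `scripts/acceptance.py` reports how often P_Conj and K_ScCh
jointly reach the top three.

The uncertainty cloud draws every non-anatomical parameter (including
M_Released and T) independently and uniformly in ±10% of nominal —
"randomized in a ±10% range" is read with the minimal-assumption
uniform distribution; the distribution is a config option. N = 400
seeded runs; the ensemble stores the pointwise min/max envelope plus
the 2.5/50/97.5 percentiles per compartment (full per-run storage
behind a flag, since 400 dense week-long trajectories are bulky). The
envelope is widest near each compartment's peak and ~10× narrower by
day 7 — parameter uncertainty perturbs the transient, not the washout.

## Synthetic data

The generators are pure functions of (spec, seed) producing cumulative
release curves and aqueous decay series from the same closed forms the
fitters assume, with optional multiplicative Gaussian noise
(value·(1+ε), ε ~ N(0, CV²), default CV 10%) — assay errors scale with
magnitude; negative values are clipped to zero and counted.

**Sampling design matters for identifiability.** The default protocol
is dense-early geometric sampling (t = 0, then span/64 up to the span,
roughly doubling), as kinetic studies use. A linearized-covariance
analysis of the unweighted least-squares estimator shows why: with
n = 10 and 10% multiplicative noise, uniformly spaced sampling leaves
CV(T̂) at 17–18% for any span (most samples sit on the plateau, which
carries no kinetic information), while the dense-early design achieves
≈ 13.8%; Monte-Carlo recovery matches (bias < 1.5%, CV(M̂) ≈ 6%,
CV(T̂) ≈ 13–15%).

What the generators emulate — and do not: they produce single-curve
measurement noise around the true kinetic model. They do not emulate
inter-animal random effects, tissue-extraction bias, model
misspecification (multi-exponential or Weibull release), or sampling
below the assay quantification limit. Passing recovery tests therefore
demonstrates the fitters are correct and well-conditioned under the
assumed error model, not that real in-vivo variability is captured.

## Problem sizes and runtime

Defaults were chosen so the full test suite and the acceptance script
each run in well under a minute on a single CPU: 50 lens nodes (with a
three-level convergence check), 1009 output points over 7 days, 200
Monte-Carlo fit replicates, 400-run uncertainty ensembles. One
release-mode week costs ~70 ms; a diffusion-mode week ~0.2 s.

## Known limitations

- Release mode ties the model to an in-vivo-derived F; a purely
  diffusive lens needs no fitting parameter.
- No active transport or metabolism: retinal clearance of lipophilic
  drugs is likely underestimated at late times.
- Small-molecule assumptions throughout; no macromolecules, carriers,
  permeability enhancers or prodrugs.
- Rabbit parameters only are bundled; human use requires a full
  parameter set from the user.
- The epithelium diagnostic requires K_Ep values that are typically
  tuned, not measured; without them the series is reported missing.
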