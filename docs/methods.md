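# Methods

## Structural models

All three systems share the same architecture: a linear PK block with
first-order absorption from an intramuscular depot, an optional linear link
compartment, and an inhibitory indirect-response (turnover) model for the
biomarker.  Coupling is strictly one-way — the biomarker never feeds back on
the drug — which the implementation exploits: the PK and link concentrations
after a single dose are exponential sums and are evaluated in closed form
(`ExpSum`), and only the turnover state is integrated.

Units: doses mg/kg at the interface (μg/kg internally), volumes ml/kg,
concentrations μg/ml, time h, biomarker in percent-of-control units.  This
makes the bundled typical-value tables directly pluggable.

* One-compartment PK: Bateman form `C(t) = A·(e^{−Ke t} − e^{−Ka t})`,
  `A = dose·Ka/(V·(Ka−Ke))`.  Parameter sets with `Ka ≈ Ke` (relative
  tolerance 1e−9) are rejected as degenerate rather than switching to the
  `t·e^{−kt}` limit: the flip-flop case never arises for these drugs and an
  explicit failure beats a silent branch.
* Two-compartment PK, micro-constant parameterisation: tri-exponential form
  with macro rates `α+β = Ke+K12+K21`, `α·β = Ke·K21` (always real and
  distinct for positive micro-constants; the smaller root is computed as
  `p/α` for stability).
* Link compartments: the ISF compartment `dCe/dt = Ke0in·C − Ke0out·Ce` and
  the effect compartment `dCe/dt = Ke0·(C − Ce)`.  The effect compartment
  uses a unit partition coefficient, the convention consistent with its IC50
  being on the plasma concentration scale.  Filtering an exponential sum
  through either link is again an exponential sum; a rate collision with the
  filter constant is resolved by a 1-in-1e9 nudge of the filter rate, which
  perturbs the curve far below every tolerance used here.
* Turnover: `dE/dt = Kin·(1 − I(Ce)) − Kout·E`,
  `I(Ce) = Imax·Ce^γ/(Ce^γ+IC50^γ)`, `Imax` stored as a fraction in (0, 1],
  `γ` fixed to 1 for the flunixin system.

### Initial condition and the castration event

`E(0) = Kin/Kout` at dose time, the standard turnover-model convention.  The
fitted baselines (88.5, 90.9, 97.7 percent-of-control for the three systems)
sit near 100, consistent with `E` being a percent-of-control scale.  The
castration/tail-dock at t = 2 h is design metadata only: the turnover
equations carry no insult term, so `Kin` is constant.

## Numerics

The turnover ODE is linear in `E` given the driver time course, so it is
solved with an exact exponential one-step scheme treating the production
term as piecewise linear over the grid (an exponential-integrator
trapezoid).  The scheme is unconditionally stable — the cortisol
effect-compartment rate `Ke0 = 15.35 1/h` poses no stiffness constraint —
and second-order accurate.  The default grid is 0.01 h, refined 10× over the
first hour because the plasma concentration crosses the flunixin IC50
(0.059 μg/ml) within minutes of dosing; with this grading, halving the step
changes the biomarker by < 1e−5 relative, and the fast path agrees with a
tight LSODA integration of the full coupled system to ~1e−6 (PK exactly,
biomarker to ~2e−5).  Cumulative products in the recurrence are chunked so
no intermediate exponential exceeds e³⁰ (overflow guard for large
`Kout·horizon` during estimation).  Estimation uses a 0.1 h grid: residual
error of ~10% dominates at that scale and the coarser grid keeps the inner
optimisation cheap.

## Statistical layer

Inter-individual variability is exponential/lognormal, `P_i = θ·exp(η_i)`,
`η_i ~ N(0, ω²)` independent per parameter (diagonal ω).  IIV is reported as
the lognormal CV, `IIV% = 100·√(exp(ω²)−1)`, the dominant pharmacometrics
convention; the inverse is `omega2_from_percent`.  Residual models:
multiplicative (`obs = pred·(1+ε)`) for drug concentrations and for both
ketoprofen biomarkers, Poisson-type (`obs = pred + √pred·ε`) for the
flunixin cortisol stream; σ for that stream defaults to 1.0, giving ≈10% SD
at a baseline near 100, commensurate with the multiplicative σ = 0.1 of the
other streams.  Negative simulated observations are retained (they are a
property of these error models at small predictions) unless explicitly
truncated; LOQ censoring is applied downstream by the study generator.
A sampled `Imax` above 1 (possible in the lognormal tail with the published
13% IIV) is capped at the physical bound.

All randomness flows from one root generator; per-subject and per-stream
substreams are spawned from it, so draws do not depend on evaluation order.

## Estimation

FOCE with interaction, implemented as: for each subject, minimise the
conditional objective `m(η) = Σ[log 2πv + (y−f)²/v] + η'Ω⁻¹η + log det Ω`
by damped Newton with a Gauss–Newton Hessian built from finite-difference
sensitivities of the predictions; approximate `−2 log L_i` by the Gaussian
expansion around the mode, `m(η̂) − d·log 2π + log det M`, with `M` either
the Gauss–Newton expected Hessian (`approx="foce"`, default) or the full
finite-difference Hessian (`approx="laplace"`).  The outer problem maximises
the summed approximate likelihood over `(log θ, log ω², log σ)` with a
Powell direction-set search, with a soft quadratic penalty beyond ±5 log
units from the start (keeps the derivative-free search out of overflow
territory without affecting interior solutions).  Convergence follows the
Powell criteria (default `xtol` 1e−4 on the log scale, max 2000 evaluations).

Standard errors are from the finite-difference Hessian of the objective at
the optimum (`cov = 2H⁻¹`); CIs are Wald intervals on the log scale,
back-transformed, hence strictly positive — matching how such tables are
conventionally printed.  A singular Hessian marks the affected CIs
unavailable rather than failing the fit.  `AIC = OFV + 2p`,
`BIC = OFV + p·ln N_obs`, `p` counting estimated θ, ω², σ.

Sequential workflow: stage 1 fits PK (plus ISF link, when the model has one)
to the drug-concentration streams; stage 2 fits the turnover parameters
(plus the effect-compartment rate, which is informed only by the biomarker)
to the biomarker stream, conditioning each subject on their stage-1
empirical Bayes parameters (`conditioning="ebe"`, default) or on the
population estimates.  Below-LOQ observations are excluded from the
likelihood with the count logged (M1).  Multistart from jittered initial
values is available (`n_starts`); the default is a single start from the
config values — in the synthetic-recovery setting the starting values are
the generator's typical values and additional starts were not found to
change the optimum, while tripling cost.

Bootstrap resamples subjects with replacement (default 100 replicates),
refits, and reports per-parameter medians and 2.5–97.5 percentile intervals;
replicate failures are counted and more than 50% failures invalidates the
result.  The VPC simulates replicate studies at the observed design from the
fitted model and overlays observed 5th/50th/95th percentiles on the
replicate bands.  When comparing, bins containing BLQ-censored observations
are not like-for-like (the simulation is not LOQ-truncated) and the
self-consistency tests therefore evaluate only fully observed bins.

## Secondary parameters

Standard compartmental identities: `Tmax = ln(Ka/Ke)/(Ka−Ke)` with `Cmax`
from the closed form (numeric bounded maximisation for the two-compartment
curve, 1e−8 h tolerance); `t½ = ln2/k`; `Cl/F = Ke·V`; `AUC = dose/(Cl/F)`
(the 0–48 h truncation difference is < 0.01% at these half-lives); MRT
reported as `1/Ke`, the disposition convention that reproduces the published
tables, with the textbook `1/Ke + 1/Ka` available by flag.  Penetration
factor = 100·AUC_ISF/AUC_plasma; plasma-scale IC50 = ISF IC50 divided by the
penetration fraction.  Note the printed penetration (6.64%) differs from the
ratio of the printed typical AUCs (7.24%) — plausibly a median of
per-individual ratios; the package computes the model-implied ratio and also
accepts an externally supplied penetration value, and the two are labelled.

## Dose–response and ED50

Per dose on a 15-point grid ({0} ∪ 14 log-spaced points 0.1–100 mg/kg;
log spacing resolves the low-dose limb where all three ED50s lie), the
biomarker course is simulated over 0–48 h and summarised by its trapezoidal
area (AUR).  Net effect `net(d) = AUR(0) − AUR(d)` (suppression lowers the
area), percent-of-max `pct(d) = 100·net(d)/net(100)`.  Residual error is
excluded from these simulations (it is mean-zero and would only inflate AUR
variance).  In Monte-Carlo mode the AUR per dose is the mean over simulated
subjects, with the same random effects reused across doses (common random
numbers, removing sampling noise from dose-to-dose contrasts); the
typical-value mode simulates the θ subject and is deterministic.

ED50 and the percent response at an arbitrary dose are read from a sigmoid
fitted through the simulated points.  The default is the one-site binding
curve with Hill slope fixed to 1 through the origin — the standard model of
mainstream dose–response software, and the readout whose (ED50, %-at-label)
pairs are exactly self-consistent in the published results, indicating both
numbers were read off such a fit.  A free-slope Hill fit and a log-linear
interpolation fallback are selectable, and the method used is recorded on
the curve.  Comparing modes on all six published quantities, the
typical-value curves match uniformly better than Monte-Carlo means, so the
reproduction pipeline reports typical-value results with the Monte-Carlo
values alongside.

Known limitation: for the ketoprofen–cortisol system the published
ED50/%-at-label pair is not reproducible from the published PD parameters
under this procedure in any mode or readout examined (the gap is ~2× in
dose scale, while the same code reproduces the other two systems within
~±10%); the discrepancy survives changes of AUR window, initial condition,
averaging convention, and interpolation method, and appears intrinsic to the
published numbers.

## Synthetic studies

The generator emulates the study design the analysis assumes: 8 piglets per
group, one IM dose at t = 0, castration at 2 h (metadata), dense plasma
sampling over the absorption phase (0.25–2 h) then out to 48 h, sparser
ISF/biomarker schedules, and LOQ censoring (plasma ketoprofen 0.05 μg/ml,
ISF ketoprofen 0.001, flunixin 0.0005); censored records carry the LOQ value
and a BLQ flag.  Exact clock times are package defaults (config-overridable)
chosen so the absorption half-life (~0.1 h) is identifiable.  Biomarker
observations are generated directly on the percent-of-control scale (the
model's `E`); the `percent_of_control` transform (ratio mode
`100·treated/geomean(control)` by default, difference mode selectable) is
provided for emulating the raw-scale workflow against a simulated untreated
group, and the two routes agree up to the control-group noise.  What passing
synthetic-recovery tests show is that the estimation machinery is consistent
with its own generative assumptions at the study's size and noise level —
not that real piglet data obey them: the generator has no insult dynamics
around castration, no assay-specific error structure, no dropout unless
enabled, and exactly the lognormal/multiplicative noise the estimator
assumes.

## Problem sizes used in the shipped checks

Dose–response: 15 doses, 0.01 h grid, n = 1000 subjects/dose in Monte-Carlo
mode.  Parameter recovery: 20 seeded replicates per system of the 8-subject
design, sequential fits capped at 400 objective evaluations from the config
starting values.  Bootstrap: 100 replicates.  VPC: 100–200 simulated
replicate studies.
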