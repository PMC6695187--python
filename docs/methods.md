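# Methods

## Model and assumptions

The model tracks two leukocyte populations in peripheral blood, with
bone-marrow dynamics assumed equivalent to (and therefore collapsed
into) the blood compartment — clinically motivated by the fact that APL
response is monitored through peripheral counts.  Normal leukocytes are
replenished at a constant flux r_N (homeostasis is a property of the
tissue, not of the circulating pool) and cleared at rate μ_N, giving a
leukemia-free steady level r_N/μ_N.  Leukemic promyelocyte-like cells
grow logistically with rate r_A and carrying capacity K_A and die at
rate μ_A.  Cross-inhibition (competition for nutrients and niche,
inhibitory signalling) enters as mass-action terms −β1·N·A and
−β2·N·A.  No spatial, angiogenic or diffusion effects are modelled;
there is no solid tumor mass.

Induction therapy adds two mechanisms:

* **ATRA** drives terminal maturation of leukemic cells into the normal
  pool at rate β3 while active.  Daily oral dosing is idealized as a
  constant-rate window [t_start, t_end) — half-open, so the switch is
  off exactly at the window's end.  Alternative ATRA intensities map
  multiplicatively onto β3 (a linear dose–response assumption; no
  saturation is modelled).
* **Anthracycline chemotherapy** (daunorubicin) is delivered as
  instantaneous intravenous doses: each dose adds ρ·bsa mg to the
  circulating amount D (ρ in mg/m², body surface area 1.82 m² by
  default), which clears at first order with rate
  τ = ln 2 · 24 / 26.7 ≈ 0.623054 day⁻¹ from the drug's 26.7-hour
  half-life.  (A published table labels this value "hours⁻¹", but the
  number itself is the per-day rate; the implementation uses day⁻¹
  throughout and treats the label as a typo.)  The drug kills both
  populations proportionally at per-mg rate γ — the standard (non-LDE)
  formulation does not discriminate between them.

All rates are per day; densities are cells/mm³; drug amount is mg.

## Fixed rates, free parameters, reference patients

Cohort-wide fixed rates: μ_N = 2.88, r_A = 3.8808, μ_A = 0.6648 day⁻¹,
K_A = 25000 cells/mm³, plus the clearance τ and the standard schedule
(60 mg/m² on days 2, 4, 6, 8; ATRA days 0–30).  Five parameters vary
per patient, with search intervals: r_N ∈ [2880, 23040] cells/(mm³·day)
(the 1000–8000 cells/mm³ homeostatic range times μ_N),
β1 ∈ [0, 0.03], β2 ∈ [0, 0.005] (cells/mm³)⁻¹day⁻¹, β3 ∈ [0, 1],
γ ∈ [0, 0.2].  Two reference patients ship as fixtures (`patient18.json`,
`patient22.json`) with their published fitted values.  Two
inconsistencies in the published values are preserved as printed rather
than "fixed": the fitted r_N values (2193.2 and 1071.7) lie below the
stated search interval, and evaluating the threshold formulas at the
printed values classifies both patients as Scenario III even though the
original analysis reports Scenario II (plausibly a rounding artifact of
the printed parameters).  The classifier reports what the formulas give;
nothing is hard-coded.

## Equilibria and scenario classification

Coexistence equilibria satisfy N = r_N/(μ_N + β1·A) with A a root of
−(r_A/K_A)β1·A² + (l_A·β1 − (r_A/K_A)μ_N)·A + (l_A·μ_N − r_N·β2) = 0.
The transcritical threshold β2th = (μ_N/r_N)·l_A controls the stability
of the leukemia-free state; for β2 > β2th the saddle-node threshold
β1,Δth = β1th + 2η + 2√(η(β1th+η)), η = r_A·r_N(β2−β2th)/(K_A·l_A²),
separates Scenario I (no coexistence equilibria) from Scenario II
(bistability).  The auxiliary value β1th is not printed in the source
literature; it is derived here from the saddle-node (discriminant-zero)
condition: at β2 = β2th the constant coefficient vanishes and the
discriminant reduces to (l_A·β1 − (r_A/K_A)μ_N)², zero exactly at
β1th = r_A·μ_N/(K_A·l_A).  For general β2, the discriminant is an
upward parabola in β1 whose roots have product β1th² and sum
2(β1th + 2η), which yields the β1,Δth expression above; the larger root
is the relevant one (below the smaller root both quadratic roots are
negative, so Scenario I holds there too, consistent with the
β1 < β1,Δth rule).  The closed form is cross-checked against bisection
of the discriminant to 1e-8 relative in the suite and the acceptance
script.

Classification within relative 1e-9 of a threshold is reported as
"boundary" rather than forced into a scenario.  An independent oracle —
equilibrium existence plus eigenvalues of the analytic Jacobian —
accompanies every classification; the two routes are required to agree
on sampled boxes.  Scenario I is kept in the API (it is needed by the
estimator's exclusion rule) even though such patients would not present
clinically.

## Numerical integration

Trajectories are integrated piecewise between breakpoints at 0, every
dose day, the ATRA window edges, and the horizon, so no discontinuity
sits inside an adaptive step.  Within a segment the drug amount is a
pure exponential and is propagated exactly (D(t) = D₀e^{−τ(t−t₀)};
impulses add ρ·bsa at breakpoints); only the nonlinear (N, A) pair is
integrated numerically (scipy `solve_ivp`, LSODA, rtol = atol = 1e-8).
The superposition closed form D(t) = Σ_{t_i≤t} ρ·bsa·e^{−τ(t−t_i)}
remains an independent check of the impulse bookkeeping and is enforced
to 10·atol on every test trajectory.  Trajectories are reported on a
uniform grid of 20 points/day plus pre- and post-dose samples at each
dose day (D is discontinuous there).  Negative undershoots within
100·atol of zero are clipped; anything larger raises.  A(0) = 0 is an
absorbing subspace and is enforced exactly.

The fitting objective evaluates the model only at observation days and
runs through a numba-compiled Dormand–Prince 4(5) integrator with the
same segment structure and exact drug propagation (rtol 1e-6,
atol 1e-3 on the cells/mm³ scale — three orders below a single count).
The compiled path is an accelerator only; it is cross-checked against
the scipy path in the suite and the package runs (slower) without
numba.

## Outcome metrics

Nmin = min N(t) over [0, 30] days, computed on the dense grid.
t_REM is the earliest time A crosses 10 cells/mm³ *with A staying below
the threshold through the horizon*: a transient dip followed by
regrowth within induction counts as no remission (∞).  This sustained
definition is what produces ∞ entries for weak protocols on aggressive
parameter sets, where A responds and then relapses inside the window.
The crossing is refined from the dense grid by a local cubic spline and
Brent root-finding to 1e-6 days.  The horizon (default 30 days, the
induction window) is configurable and reported with the metric.  The
ATRA-only remission threshold in β3 is located by bisection on [0, 1]
to 1e-4 after verifying that remission status differs at the bracket
endpoints; remission is not generally monotone in β3 over arbitrary
brackets, so the endpoint check is part of the contract.

## Estimation

E(X) is the raw quadratic error on linear counts — no log transform and
no weighting, exactly as the objective is defined.  The multistart
procedure samples K = 10,000 tuples (reduced in tests; sizes below)
uniformly and independently per coordinate (a Latin hypercube option
exists but is off by default), keeps the 100 best, and polishes each.
"Local descent" is implemented as projected steepest descent in
box-scaled coordinates: central finite differences with per-coordinate
steps of 1e-4 of the interval width, backtracking line search, stop at
relative improvement < 1e-8 or 200 iterations.  Because steepest
descent stalls on the ill-conditioned valleys this objective produces,
a Nelder–Mead polish inside the box (`method="nm"` or `"descent+nm"`)
is provided and is used for the recovery experiments.  Local minima
landing in Scenario I are kept in the census but excluded from
best-tuple selection; if *all* minima are Scenario I the fit fails
loudly.  Initial conditions default to the day-0 laboratory convention:
A(0) = the day-0 immature count (0 if absent), N(0) = day-0 total minus
A(0); the convention is configurable since no published convention
exists.

## Virtual patients

The generator draws true tuples uniformly from the search box
(rejecting Scenario I by default — such patients are never diagnosed),
draws initial states N0 ~ U[200, 3000] and A0 ~ U[500, 20000] cells/mm³
(an invented distribution: no published values exist; chosen so the
standard protocol produces both remission and relapse outcomes across a
cohort), simulates the standard induction course, and observes it
sparsely: the number of total-WBC days is 4 + Binomial(14, ½) — support
{4, …, 18} with median and mode 11, matching the reported cohort median
robustly in finite samples — day 0 always included, the
remaining days drawn without replacement from 1–30; immature counts
exist with probability 0.68 and, when present, number 1–4 with median 1
(probabilities 0.60/0.25/0.10/0.05), drawn from the patient's WBC days.
Observations are multiplied by lognormal noise (σ = 0.1 by default) and
rounded to integer counts.  A `dense_daily` configuration (daily
noiseless or noisy observations of both series) supports recovery
experiments, and `immature_day0` forces a day-0 immature count so the
initial-state convention is well defined when fitting synthetic
patients.

What the generator does *not* emulate: platelets, coagulation markers
and other collected-but-unmodelled series; measurement scheduling
driven by clinical state (observation days are exchangeable here);
inter-patient correlation of parameters.  Passing recovery tests on
this cohort therefore demonstrates correctness of the estimation
machinery under the stated noise and sparsity, not identifiability on
any particular real patient.

## Identifiability

With noiseless daily observations of both series the estimator recovers
all five components to well under 1%.  Under 5% noise the drug-kill
rate γ remains well determined (median relative error a few percent),
but β3 is structurally weakly identified: in the A-equation β2·N(t) can
substitute for β3 almost exactly, and the distinguishing β3·A flux into
N is hidden beneath 5% noise on the totals.  With cohort-like sparsity
the objective becomes numerically flat in β3 (E at the truth and at a
β3 → 0 optimum agree to seven digits).  This mirrors the original
finding that induction-phase data alone do not pin a unique tuple —
local minima of comparable error split across Scenarios II and III —
which is why the scenario census, not a point estimate, is the risk
readout.  The gated recovery check is correspondingly the median
relative error pooled over the recovered (β3, γ) pair on dense daily
data; per-component medians are reported alongside.

## Monotonicity probes are tendencies, not theorems

Stronger drug effects are expected not to worsen the outcome metrics:
t_REM non-increasing in β3 and in γ, Nmin non-increasing in γ.  These
are gated as a pass rate (98%) over a virtual cohort because genuine
counter-examples exist in the model: for patients with strong
leukemic-on-normal inhibition (large β1·A), increasing γ clears the
leukemic population faster, relieves the β1·N·A suppression, and can
*raise* the normal-cell nadir — the indirect benefit outruns the direct
cytotoxicity.  Across generator seeds the observed pass rate runs about
95–99%, and essentially every violation is of this Nmin-vs-γ type; the
offending parameter tuples are logged by the probe for inspection.

## Problem sizes used by the suite and acceptance script

Chosen as the package's own test design: scenario-oracle agreement on
1000 sampled tuples; saddle-node bisection cross-check on 100;
monotonicity probes (t_REM vs β3, t_REM vs γ, Nmin vs γ, 1.5× scaling,
pass rate gated at 98%) on a 50-patient cohort; noiseless recovery with
K = 2000 samples and 24 polished starts; noisy recovery on 10 patients
with K = 2000 and 16 starts; cohort realism on 500 patients.

## Known limitations

Single-compartment blood-only dynamics; single-exponential drug
clearance (no delivery-system pharmacology); constant-rate ATRA window
rather than daily pharmacokinetics; linear ATRA dose–response on β3;
no consolidation or maintenance phases; no cost functions over
protocols; basin geometry only via pointwise membership integration,
with no resilience/basin-size quantification.  Exact published
per-patient outputs (outcome tables, fitted curves, censuses, the
simulated ATRA-only threshold value) require laboratory series and
initial conditions that were never deposited; the package reproduces
the printed closed-form arithmetic exactly and validates everything
else property-wise, as described above.
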