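# apldyn

Dynamics of acute promyelocytic leukemia (APL) under induction therapy:
a two-population competition ODE model of normal and leukemic leukocytes
in peripheral blood, with impulsive anthracycline chemotherapy and a
switched ATRA maturation term; qualitative outcome classification of the
untreated system; induction-protocol simulation with cytotoxicity and
time-to-remission metrics; multistart least-squares estimation of
per-patient parameters from sparse blood counts; and a virtual-patient
generator that emulates the data density of real induction-phase
laboratory records.

The package is aimed at mathematical oncologists and biostatisticians
studying treatment scheduling in acute leukemias, where randomized
trials of alternative schedules are impractical and *in silico*
comparison is the available tool.

## Model

Normal leukocytes N(t) and leukemic promyelocyte-like cells A(t)
(cells/mm³) compete in peripheral blood:

    dN/dt = r_N − μ_N·N − β1·N·A + β3·A·1[ATRA] − γ·D·N
    dA/dt = r_A·A·(1 − A/K_A) − β2·N·A − μ_A·A − β3·A·1[ATRA] − γ·D·A
    dD/dt = Σ_i ρ_i·δ(t − t_i) − τ·D

Normal cells are produced at a constant tissue-driven flux r_N and die
at rate μ_N; leukemic cells grow logistically (rate r_A, capacity K_A)
and die at rate μ_A; β1 and β2 are the cross-inhibition rates.  During
the ATRA window (days 0–30 of induction) leukemic cells mature into
normal ones at rate β3.  Chemotherapy doses ρ_i (mg) delivered at days
t_i decay at rate τ and kill both populations proportionally at per-mg
rate γ.

Untreated, the system has the leukemia-free equilibrium
P0 = (r_N/μ_N, 0) and up to two coexistence equilibria P1, P2; three
phase portraits arise, governed by the transcritical threshold
β2th = (μ_N/r_N)·l_A (with l_A = r_A − μ_A) and the saddle-node
threshold β1,Δth = β1th + 2η + 2√(η(β1th + η)) with
η = r_A·r_N·(β2 − β2th)/(K_A·l_A²) and β1th = r_A·μ_N/(K_A·l_A):

* **Scenario I** — leukemia is cleared from any initial state;
* **Scenario II** — bistable: the saddle P1's stable manifold separates
  the remission (P0) and disease (P2) basins;
* **Scenario III** — leukemia develops from any state with A(0) > 0.

Per-patient parameters X = (r_N, β1, β2, β3, γ) are estimated by
minimizing the quadratic error between the simulated course and the
laboratory series,

    E(X) = Σ_j (N(t_j)+A(t_j) − L_j)² + Σ_k (A(t_k) − I_k)²,

via uniform sampling of K tuples in the search box, selection of the
best 100, local descent from each, and selection of the smallest-E
local minimum outside Scenario I.  The scenario census of the 100 local
minima doubles as a relapse-risk indicator.

Protocols are graded by **Nmin** = min N(t) over the 30-day window
(hematological toxicity) and **t_REM**, the first time A falls below
10 cells/mm³ *and stays below it* through the window (∞ when the
response relapses within induction).

## Worked example

```python
import apldyn as a

# a reproducible virtual patient with known ground truth
patient = a.sample_patient(3, a.PatientConfig(noise_sigma=0.0,
                                              dense_daily=True))
model = a.APLInductionModel(patient.lab, init=patient.init)
res = model.fit(K=500, n_keep=8, seed=11, method="descent+nm")
print(res.summary())
```

prints

```
APL induction model — multistart least-squares fit
==========================================================
patient id:        synthetic-3
observations:      31 total WBC, 31 immature
initial state:     N0=1412.76, A0=9841.5 cells/mm3
samples / starts:  500 / 8
quadratic error E: 4.24759
scenario:          II
scenario census:   II: 88%, III: 12%
----------------------------------------------------------
parameter       estimate    minima p25    minima p75
r_N              4606.72       4606.72        4701.6
beta1         0.00710373    0.00710373     0.0115397
beta2         0.00400658    0.00400658    0.00429819
beta3           0.582125      0.582125      0.673026
gamma           0.018825      0.018825     0.0196834
```

The selected tuple reproduces the generating parameters
(r_N = 4606.69, β1 = 0.007104, β2 = 0.004006, β3 = 0.58216,
γ = 0.018826) to within ~0.01%: the residual error E ≈ 4.2 is the floor left by
rounding observations to integer counts.  The patient is classified as
Scenario II (bistable), matching the ground-truth label, and the census
shows how many local minima would instead imply unavoidable relapse
(Scenario III) — the spread of the minima is the dispersion measure this
procedure supports.

Downstream, `res.compare_protocols()` produces the 13-row outcome table
(standard induction P0, reduced/split chemo P1–P8, ATRA variants Q1–Q4)
with Nmin and t_REM per protocol, and
`a.atra_threshold(...)` locates the smallest ATRA maturation rate that
still achieves sustained remission without chemotherapy.

A thin CLI mirrors the library: `apl simulate`, `apl classify`,
`apl fit`, `apl compare-protocols`, `apl atra-threshold`,
`apl make-synthetic`.

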