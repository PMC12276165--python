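# Methods

## The model

`graftdyn` implements a six-state mechanistic model of T cell-mediated
rejection of a transplanted liver, set in peripheral blood roughly one year
after transplant, at the moment immunosuppression no longer holds the
response in check.  The states are healthy graft hepatocytes L (absolute
cells, whole liver), alloantigen-presenting cells A, activated helper T
cells T_H, activated cytotoxic T cells T_C, regulatory T cells T_R (all
cells/µL), and interleukin-2 I (ng/µL).

The equations (per day):

    dL/dt   = -δ_L L · [α_CL T_C/(β_CL + T_C)]
    dA/dt   = λ_L δ_L L (1 + α_CL T_C/(β_CL + T_C)) - δ_A A
    dT_H/dt = [α_AH A/(β_AH + A)]·[1 - (α_RA T_R/(β_RA + T_R))(1 + α_IRA I/(β_IRA + I))]
              + γ_H T_H (1 - T_H/K_H)·[α_IH I/(β_IH + I)] - δ_H T_H
    dT_C/dt = α_HC T_H/(β_HC + T_H) + γ_C T_C (1 - T_C/K_C)·[α_IC I/(β_IC + I)]
              - δ_C T_C
    dT_R/dt = s_R - δ_R T_R·[1 - α_IR I/(β_IR + I)]
    dI/dt   = α_CI T_C/(β_CI + T_C) + α_HI T_H/(β_HI + T_H)
              - λ_C·[T_C proliferation term] - λ_H·[T_H proliferation term]
              - λ_R·[T_R survival term] - δ_I I

Modeling assumptions worth knowing about:

* **Homeostasis of the graft.**  Hepatocyte production and natural death are
  assumed equal, so the source rate s_L cancels and the only net change in L
  is immune-mediated killing.  Hence dL/dt ≤ 0 identically — the model
  describes rejection, not recovery.
* **Saturation everywhere.**  Every cell–cell or cytokine effect is a
  Michaelis–Menten term αx/(β + x): bounded by α, half-maximal at x = β.
* **IL-2 bookkeeping.**  The three IL-2 internalization losses are exactly
  λ_C, λ_H, λ_R times the corresponding proliferation/survival terms of the
  T cell equations: IL-2 consumed is proportional to cells produced (or
  Tregs kept alive).  `decompose_pathways` exposes every labelled factor and
  the recombination rule, and tests assert the identity term-by-term.
* **Units are mixed deliberately.**  L is a whole-organ count while the other
  populations are blood concentrations; λ_L (1/µL) performs the conversion in
  the APC source.  No internal rescaling is applied.
* **Constraints.**  All parameters are non-negative and α_IR ≤ 1 (hard
  errors otherwise).  The suppression bound α_RA(1 + α_IRA) ≤ 1 is *violated*
  by the nominal values (0.4 × 3 = 1.2); the helper-activation bracket can
  therefore go slightly negative at large T_R and I.  We evaluate the
  equations exactly as written — no flooring — and surface this as a warning,
  because silently clipping would change the dynamics.  A parameter set to
  exactly zero is admitted with a warning as a diagnostic switched-off limit
  (used by the one-at-a-time and validation tooling).

## Parameterization

All 35 nominal parameters and the 6 initial values are rebuilt at import
time from the literature constants they were originally derived from:
growth rates as ln2/doubling-time, loss rates as 1/lifespan or
ln2/half-life, carrying capacities as the 40% antigen-specific share of
measured T cell counts, the Treg source from circulating naive T cell
numbers times a fitted differentiation rate, and the proportionality
constants λ from cell-culture dosing arithmetic.  Each derived value is
rounded to the printed precision (3 significant figures unless the table
prints otherwise) and asserted equal to the printed value; the printed
value is then what simulations use, keeping results digit-comparable to the
published table.

Three published inconsistencies are carried as provenance flags rather than
resolved: the λ_H culture procedure yields 6.3e-5 ng/cell while the table
stores 6.3e-6 (table value used); the cited 15-day Treg lifespan gives
δ_R = 0.0667/day while the table prints 0.0658 (table value used, no
round-trip asserted); and A0 = 0.75 × 10.79 = 8.0925 is printed as 8.0
(printed value used).  α_HI = 70.7 is adopted directly because the per-cell
production rate behind it is not printed (implied ≈ 1.01 ng/cell·day).

## Numerics

The system is mildly stiff: IL-2 turns over at δ_I = 166/day against
δ_L = 0.005/day, and state magnitudes span 13 orders.  Single trajectories
use adaptive LSODA with rtol 1e-8 and per-state absolute tolerances
(1e2, 1e-8, 1e-8, 1e-8, 1e-8, 1e-12) matched to state scales.  Negative
excursions are never clipped; any state below −100× its absolute tolerance
aborts the run, since clipping masks solver or model errors.  The day-30
QOI is read from dense output, never from the nearest reporting-grid point;
the default 0.1-day grid is cosmetic.

Two independent integration paths exist for cross-checking: a fixed-step
classical RK4 reference (`rk4_reference`, default step 1e-4 day), and the
adaptive solver; they agree to better than 1e-6 relative on all states on
the nominal run.

GSA designs need ~7.6e4 model evaluations at the desk-scale sample counts,
so `evaluate_design` advances the whole sample block simultaneously with a
vectorized fixed-step RK4 (step 0.005 day, well inside the explicit
stability limit of the fastest sampled rate, 1.5 × δ_I = 249/day).  Against
the adaptive solver this batch path is accurate to ~1e-5 relative on L(30)
across the entire ±50% sampling box — two orders of magnitude below the
Monte-Carlo noise on the indices it feeds.

## Sensitivity analysis

Parameters are sampled independently and uniformly on [50%, 150%] of
nominal (initial values excluded, since an intervention at time zero cannot
change them).  The design is the Saltelli layout built from a scrambled
Sobol' sequence in 2k dimensions (first k columns → block A, last k →
block B, plus the k column-swapped blocks), N(k+2) evaluations total.
First-order indices use the Saltelli-2010 estimator
mean(f_B·(f_AB − f_A))/V and total indices the Jansen estimator
mean((f_A − f_AB)²)/2V — the standard lowest-variance choices consistent
with an N(k+2) design.  Indices are reported unclipped; small negative
first-order estimates are ordinary Monte-Carlo noise.  Reported standard
errors are per-term standard deviations over √N, adequate for judging
whether two indices are distinguishable.

The estimators are validated against two closed-form oracles (an additive
linear function, and the Ishigami function with its analytic variance
decomposition) within 3 Monte-Carlo standard errors.

Ranking uses the total index, descending, with ties broken by first-order
index and then name so the ordering is deterministic.  The convergence
protocol re-estimates indices over an increasing schedule of base-sample
counts (default 512/1024/2048, a desk-scale version of the published
100k–175k protocol) and reports whether the top-k order is stable.

The variability experiment draws one seeded uniform sample over all 35
ranges and evaluates it three ways — as-is, with only the six
most-influential parameters varying (others pinned at nominal), and with
only the remaining 29 varying — so the three QOI distributions share one
underlying draw and their variances are directly comparable.

### Scale and known limitations

* Default GSA sample counts (N = 2048 base samples, ~7.6e4 evaluations;
  10 000 draws for the variability experiment) are desk-scale choices; the
  published analysis used N = 175 000 (6 475 000 evaluations).  At N = 2048
  the estimated total indices of the 5th/6th-ranked parameters (γ_C and
  α_IC, both ≈ 0.05) are separated by less than their Monte-Carlo error, so
  their mutual order is not reliably resolved at this scale; the top-4
  order and the top-6 set are stable.  Larger N is a flag away
  (`graftdyn gsa --n-base ...`).
* The total indices of the 7th–16th ranked parameters are genuinely of
  order 1e-2 — small but not negligible; only the trailing ~19 parameters
  have indices consistent with zero.
* No second-order indices, no alternative screening methods, no therapy
  terms, no spatial/multi-compartment structure, and no fitting to patient
  data: the nominal parameterization is a literature composite, and the
  sensitivity ranking is a statement about this parameterization, not about
  any individual patient.
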