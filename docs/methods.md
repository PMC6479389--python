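# Methods

## Model structure

The simulator propagates a closed cohort of never-users through a finite
state space in 5-year steps. A state is a use category — `NEVER`,
`CUR_CIG`, `CUR_MST`, `DUAL`, `FORMER_CIG`, `FORMER_MST`, `FORMER_DUAL`
(plus `FORMER_ALL` for custom catalogues) — expanded by duration memory in
5-year bins: years smoked (YSM), years since quitting smoking (YQSM),
years of MST use, and years since quitting MST. Published descriptions of
this model family enumerate a fixed list of ~29 states; here the expansion
is data-driven (category × reachable duration combinations), which
subsumes any such fixed list and is required anyway because the mortality
models read YSM/YQSM continuously. The fourth duration clock (time since
quitting MST) is an extension of the minimal three-clock bookkeeping: the
former-MST hazard is excess-scaled off the former-smoker model, which
needs a since-quit covariate for the MST spell.

Bookkeeping per interval, applied to the category occupied *during* the
interval: smoking categories (`CUR_CIG`, `DUAL`) accrue YSM; MST
categories (`CUR_MST`, `DUAL`) accrue MST time; any non-smoking interval
after smoking has begun accrues YQSM, and any non-MST interval after MST
use accrues the MST quit clock. Clocks never decrease. Dual users accrue
both use clocks simultaneously, so a later exclusive-MST or former state
retains the full smoking history.

Staying in a category is never an explicit edge; it is the residual
probability after all outgoing flows, which makes per-source row sums ≤ 1
the single table invariant.

## Transition sub-model

Base Case rates are per-5-year probabilities per (age band, edge). The
Modified Case is derived, not separately specified:

* each key edge is scaled by the relative difference between test and
  control pre→post intention ratios,
  `((test_post/test_pre) − (control_post/control_pre))/(control_post/control_pre)`;
  the bundled proportions give −5% (MST initiation), +21% (switching),
  +24% (dual uptake) and +6% (dual→exclusive MST). The unrounded deltas
  (e.g. +20.82%) are the default; `use_rounded_deltas` reproduces the
  whole-percent worked examples exactly (1.4% × 1.21 = 1.694% ≈ 1.7%).
* the *would-be smoker* fraction (default 1%) of the Base Case
  cigarette-initiation flow and the *would-be quitter* fraction (default
  5%) of the Base Case cigarette-cessation flow are rerouted to MST use.
  Diversions reroute flow — per-source outgoing mass is conserved — and
  are treated as additive to the ordinary switching/initiation edges.

Rate uncertainty redraws initiation and cessation entries (edges out of
`NEVER` or into a `FORMER_*` category, positive entries only) from a
truncated normal on [0, 1] with sd 0.02 probability points, via
inverse-CDF on content-keyed uniforms: each entry's draw is seeded by
(seed, hash(age, source, target)), so the Base and Modified tables receive
common random numbers on shared edges and identical tables draw
identically — the null comparison is exactly zero. Rows whose drawn sums
would exceed 1 are redrawn wholesale.

## Mortality sub-model

Deaths in exposure cells are modelled as Poisson with a log link and
offset `log(person_years/100,000)`; rates are per 100,000 person-years.
Never users use {1, AGE, AGE²}; current smokers add {YSM, YSM×AGE}; former
smokers add {YSM, YQSM, YSM×AGE, YQSM×AGE}. AGE is the 5-year band
midpoint; bands are half-open [a, a+5). Fitting is maximum likelihood
(statsmodels GLM); the uncertainty layer samples coefficients from the
asymptotic normal approximation to the posterior under a flat prior, with
a random-walk Metropolis sampler available for verification
(`MortalityResults.sample_posterior_metropolis`).

MST carries no fitted model. Its multiplier is excess-risk scaling:
`1 + ERR·(RR_smoking − 1)` with ERR 0.09 (current) and 0.04 (former),
where the smoking RR is evaluated with YSM set to the MST duration (a
configurable assumption, `mst_ysm_override`, since no MST-specific
duration model exists). The excess-risk form is used rather than a plain
RR product because it reproduces the ERR = 0 (never-user risk) and
ERR = 1 (smoker risk) limits identically. A pathway hazard is the
never-user baseline times one multiplier per exposure component: active
smoking (dual use counts as full cigarette risk, and its MST component is
not additionally applied), a completed smoking spell (former-smoker RR at
the pathway's YSM/YQSM), current MST use, and a completed MST spell.

Rate → probability conversion is exponential: `S₅ = exp(−5·λ/100,000)`,
guaranteeing S ∈ [0, 1] at any hazard (the linear alternative
`1 − 5λ/100,000` differs materially only at the oldest ages).

## Cohort engine

Propagation is deterministic expected-value mass flow, not agent
simulation: at cohort size 10⁶ demographic noise is irrelevant and all
reported uncertainty is parametric. Within a step, transitions are applied
first and survival second, using the *destination* state's hazard at the
band midpoint (`hazard_timing="source"` switches to the source state's
hazard). Mass conservation — survivors plus cumulative deaths equal the
initial size — is asserted at every step to 10⁻⁹ relative and verified
independently by an exhaustive-pathway oracle on small catalogues.

Scenario comparison draws one sub-seed per replicate, applies it to both
scenarios' rate tables and to a shared coefficient draw (common random
numbers), and reports the per-band mean, SD and equal-tailed 2.5/97.5
percentile interval of the survivor differences. Attribution re-runs the
comparison with one Modified-Case component at a time (each intention
edge, then each diversion), sorted ascending; single-edge effects interact
and are not asserted to sum to the joint effect. The would-be-quitter
diversion is individually harmful (a diverted smoker retains more risk
than a quitter), which is visible as small negative differences at young
ages in some configurations before switching benefits dominate.

## Multi-cohort population model

Birth cohorts (5-year quinquennia, census-style sizes) enter at age band
0–4 in their birth period and are propagated independently with the rate
table of their vintage (birth-cohort-specific tables for older cohorts
where available, constant rates otherwise). A cohort born in [y, y+5)
occupies age band [a, a+5) during calendar years [y+a, y+a+5); snapshots
sum cohorts at the age each occupies that year. Totals are linear in
cohort sizes and equal the sum of single-cohort survivor totals by
construction. Deaths prevented between scenario snapshot series are summed
over ages 0–84 by default. Reference validation reports
`100·(model − reference)/reference` overall and per band.

## Life tables

From survivors l_x at band starts: closed-band person-years
`L_x = 5·(l_{x+5} + ax·(l_x − l_{x+5}))` with `ax_fraction` defaulting to
0.5 (deaths uniform within the band); the exact within-band convention is
not fixed by the published tables and changes T_x by less than one band
width. The final band is open-ended: `L = l/h` with h the closing per-year
hazard (supplied, or carried forward from the last modelled interval —
documented because the T column depends on it). T_x is the backward
cumulation of L_x and e_x = T_x/l_x. Between-scenario output reports the
l and T differences per band; the T difference computed as a difference of
columns and as cumulated L differences agree exactly.

## Sensitivity grids

Axes pin one or more edges to absolute rates (or multipliers) at the ages
where the Modified-Case table has positive rates on that edge, holding
everything else at the Modified Case, and evaluate each point with a
deterministic draw-free run. The net-neutral mask is exactly the set of
non-positive cells; no smoothing. Grid points are independent, so the
matrix is order-invariant.

## Synthetic data

Ground-truth mortality coefficients are Gompertz-like and fixed once:
never (β0 = 1.8, β_AGE = 0.095, β_AGE² = −10⁻⁴), giving ~2,900 deaths per
100,000 person-years at 70 — a plausible male all-cause baseline; current
smokers add β_YSM = 0.045, β_YSM×AGE = −3.5·10⁻⁴ (RR ≈ 2–3 at mid-life,
declining at the oldest ages); former smokers add β_YQSM = −0.02,
β_YQSM×AGE = 1.5·10⁻⁴ (risk decays toward baseline after quitting).
Exposure is 200,000 person-years per covariate cell on a factorial grid
consistent with each group's constraints; deaths are Poisson draws from
the truth. Transition profiles use the published headline rates (switch
1.4%, MST initiation 1.6% at adolescent/young-adult ages) with remaining
rates set once to values plausible for U.S. males (youth cigarette
initiation peaking at ~10–12% per 5 years, cessation rising with age from
5% to 15%, dual-use resolution 17.4% to exclusive MST); relapse defaults
to zero because no reliable estimate exists. All randomness flows through
one seeded generator per output.

What the generator does *not* emulate: real transition tables vary by
birth cohort and period; real exposure data are observational (confounded,
unbalanced, reweighted to vital statistics); intentions map imperfectly
onto behaviour. Passing tests therefore demonstrate correctness of the
*machinery* — propagation, composition, estimation — under known truth,
not calibration of real populations.

## Problem sizes and numerical choices

The bundled single-cohort runs follow 10⁶ members over 18 five-year steps
(13 → 103, final band open-ended); the expanded state space reaches ~10⁵
states and one deterministic run takes on the order of a second. Tests
and examples use a few to a few-hundred Monte-Carlo draws — the
comparison's mean is deterministic under common random numbers, and draw
counts only sharpen the interval estimates; production runs can raise
`n_draws` (the signature default is 10,000). Degenerate inputs are
rejected loudly: all-zero death tables, increasing survivor series,
row sums above 1, missing age bands, inconsistent pathways. Ties and
corners: rates scaled above 1 are capped with a warning, derived negative
rates floored at 0; hazards are evaluated at band midpoints with the
post-transition state's durations (which therefore include the current
interval).

## Known limitations

* Temporal resolution is 5 years; within-interval transitions and partial
  durations are invisible.
* Cigarettes-per-day dose effects, cause-specific mortality, other
  tobacco products (e-vapor, cigars), poly-use of three or more products,
  female cohorts and migration are out of scope.
* The MST duration → YSM mapping in the ERR scaling is an assumption, not
  an estimate; `mst_ysm_override` exposes it.
* Relapse edges exist in the catalogue but ship with rate 0.
* The credible intervals inherit the normal posterior approximation of
  the Poisson fits; the Metropolis path exists to check it, not to
  replace it.
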