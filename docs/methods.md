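# Methods

## Model structure

The disease course of extensive-stage small-cell lung cancer is represented
by three mutually exclusive states: progression-free disease (PFD),
progressed disease (PD) and death. The whole cohort enters in PFD. Cycles
are 21 days (one treatment administration interval) over a 20-year horizon,
which at 365.25 days/year gives 348 cycles — long enough that essentially
the entire cohort reaches the absorbing state under realistic survival
inputs.

State occupancy is *partitioned* from the two marginal survival curves
rather than built from an explicit PD→death transition rate:

    Dead(t) = 1 − S_OS(t)
    PFD(t)  = min(S_PFS(t), S_OS(t))
    PD(t)   = 1 − Dead(t) − PFD(t)

This reproduces both curves exactly and avoids assumptions the available
evidence cannot support. A conventional forward Markov engine
(`simulate_markov`) is provided for comparison; with non-crossing curves it
coincides with the partitioned assignment (property-tested to 1e−6 per
cell). Because comparator curves are produced by exponentiating each curve
independently (see below), S_PFS can exceed S_OS at some times; PFD is then
clamped to S_OS, PD is set to 0 there, and the number of clamped cycles is
recorded on the trace.

Occupancy is evaluated at cycle start with no half-cycle correction. This
overstates time-in-state by at most half a cycle (≈ 10 days) relative to
the midpoint convention; with 21-day cycles the effect on 20-year totals is
well under 1%.

## Survival model

The reference (chemotherapy) arm uses the log-logistic survival function

    S(t) = 1 / (1 + exp(θ) t^κ),   κ > 0,  t in months,

whose median is exp(−θ/κ). Time is fixed to months (30.4375 days/month) so
θ has a definite meaning; cycle times convert as k·21/30.4375.

Comparator arms apply a relative-effect hazard ratio as an exponent:
S_arm(t) = S(t)^HR. For log-logistic curves this is **not** the
proportional-hazards transform; it is the convention used deliberately
throughout this pipeline (the practical interpretation: HR acts on the
cumulative log-odds-like scale of the reference curve). A consequence is
that independently powered PFS and OS curves may cross — handled by the
clamp described above.

Fitting: six candidate families (exponential, Weibull, lognormal,
log-logistic, Gompertz, gamma) are fitted to right-censored records by
maximising Σ events·log f(t) + Σ censored·log S(t). Distributions' log-pdf
and log-survival come from `scipy.stats`; optimisation is Nelder–Mead on
log-transformed parameters (θ unconstrained) with up to three perturbed
restarts plus a BFGS polish. Starting values are method-of-moments style
heuristics (event rate, median, log-time moments). Selection is by AIC
(−2ℓ + 2k) or BIC (−2ℓ + k ln n); ties break toward fewer parameters, then
a fixed family order. The log-logistic route is cross-checked in the test
suite against `lifelines.LogLogisticFitter` (its (α, β) map to
θ = −β ln α, κ = β); log-likelihoods agree to 1e−6 relative.

## Pseudo-IPD reconstruction

Digitized KM coordinates (time, survival) plus the number-at-risk row are
inverted interval-wise. A curve drop at time t is attributed to the at-risk
interval (t_j, t_{j+1}] containing t. Within each interval the algorithm
fixed-point iterates between (a) inverting product-limit ratios to get
integer event counts at the digitized drop times, given a provisional
number of censorings spread uniformly (deterministically) over the
interval, and (b) resetting the censoring count so that events + censorings
exactly equal the published decrease in the number at risk (conservation is
enforced, never approximated). Patients still at risk after the last
digitized time are censored administratively at the end of follow-up. If
the digitized drops imply more events than the risk table allows, the
offending interval is named in the error. When no risk table exists, a
stated effective sample size with censoring only after the last event can
be supplied instead (degraded mode).

Round-trip accuracy is assessed *at the digitized grid points*: between
grid points the digitization carries no information, and at n = 300 the
step-function phase mismatch alone can exceed the 0.02 tolerance without
any reconstruction error. At a 1-month grid, 300 subjects and uniform
censoring, the worst deviation across 20 seeds is ≈ 0.011.

## Economics

Cost components per cycle k with discount d_k = (1+r)^(−21k/365.25),
r = 5%/year (0–8% in sensitivity analysis):

- drug acquisition while in PFD: per-kg doses use the sex-weighted mean
  weight (0.5·69.6 + 0.5·59.0 kg by default), per-BSA doses 1.72 m²,
  carboplatin via Calvert dose = AUC·(CrCl + 25) at CrCl 70 ml/min;
  chemotherapy backbone drugs stop after a 4-cycle induction, ICIs continue
  until progression. Exact milligrams are billed by default; a
  ceil-to-pack (vial wastage) mode is available per rule.
- follow-up and best supportive care in PFD; subsequent anticancer therapy
  (modelled as a uniform per-cycle PD cost) and BSC in PD; a one-off
  palliative cost weighted by new deaths each cycle.
- grade 3/4 adverse events enter once at model entry: chemotherapy
  frequencies are scaled by the arm's AE hazard ratio (capped at 1) and
  combined as frequency-weighted sums of unit costs, and of
  disutility × duration/365.25 for the QALY decrement.

QALYs accrue at u_PFD = 0.856 and u_PD = 0.768 per year in state.
Currency is 2023 USD at 7.0467 CNY/USD; a converter is provided so CNY
inputs reproduce USD inputs exactly.

## Frontier

Strategies are sorted by ascending cost and compared stepwise to the
previous alternative: non-positive incremental QALYs at higher cost is
strict dominance; a sequential ICER above the next alternative's is
extended dominance. Dominated and extended-dominated strategies are removed
and the pass repeated until sequential ICERs strictly increase along the
survivors. Each pass is retained for export. The surviving set equals the
upper-left convex hull of the cost/QALY scatter (verified against an
exhaustive mixing oracle on 200 random instances). Negative ICERs are
reported verbatim in stepwise tables but never interpreted as
cost-effective; equal-QALY comparisons resolve by cost dominance, identical
(cost, QALY) duplicates by name with a logged warning.

## Sensitivity analysis

Plausible ranges: hazard ratios use their 95% CIs; the discount rate spans
0–8%; all other inputs ±25% of baseline. One-way DSA reruns the pairwise
ICER at each bound with everything else at base and sorts by spread;
failures at an endpoint flag the entry rather than dropping it. The
threshold search bisects to 1e−6 relative tolerance after an endpoint
monotonicity check (a midpoint inconsistent with monotone endpoints raises
and directs the user to a grid scan).

PSA distributions follow the usual assignment — gamma for costs, beta for
probabilities and utilities, lognormal for hazard ratios, uniform as
fallback — parameterised by moment matching: mean anchored at the base
value, standard deviation (high − low)/(2·1.96); hazard-ratio lognormals
match the 95% CI on the log scale. Parameters are drawn jointly and
independently (no correlation structure is published for these inputs);
because utilities are drawn independently, a draw with u_PD > u_PFD is
clamped to preserve the state ordering. Draws are reproducible from the
recorded seed. Acceptability curves report the probability of maximal net
monetary benefit (wtp·QALYs − cost) over a 0–60,000 USD/QALY grid in
500-unit steps, spanning the 15,217.00–38,042.49 USD/QALY decision range
(1.2–3.0 × per-capita GDP); ties split equally.

Subgroup runs (gender, age, ECOG performance status) re-run the full base
case with subgroup-specific OS/PFS hazard ratios, and sex-specific weight
for the gender subgroups; strategies without a subgroup HR keep the overall
value, unknown strategy names are skipped with a warning.

## Synthetic world

The original analysis's parameter workbook is not publicly deposited, so
the package ships a synthetic stand-in (`demo_workbook`) that is complete
and internally consistent: chemotherapy curves log-logistic with
(θ, κ) = (−2.5, 1.8) for PFS (median ≈ 4.0 months) and (−4.0, 1.6) for OS
(median ≈ 12.2 months, within the 8–16 month plausibility band enforced by
`SyntheticScenario`); ICI hazard ratios in the range reported by first-line
ES-SCLC trials; synthetic prices, adverse-event frequencies/costs and
non-drug costs of realistic magnitude for Chinese oncology practice.
Published constants (utilities, anthropometrics, exchange rate, discount
rate, WTP range, cycle length, horizon) live in a read-only
`PAPER_CONSTANTS` registry so provenance is machine-checkable. Cohort
generators are inverse-CDF samplers, seed-deterministic.

A green test on this world establishes that the *machinery* is correct
(conservation, closed forms, oracle agreement, recovery of known
parameters); it does not certify the original study's absolute per-strategy
costs and QALYs, which depend on undeposited inputs. The published
strategy-level (cost, QALY) table is kept as an immutable fixture and the
ICER/frontier layer is held to it at printed precision.

## Numerical choices and limitations

- Row sums of the trace are normalised and validated to 1e−9; occupancy is
  clipped at 0.
- Reconstruction censor times are uniformly spaced (deterministic), not
  random: reproducibility over realism-in-the-small.
- Recovery experiments use 20% uniform censoring (uniform(0, 100) months
  for the default OS curve, determined by quadrature).
- The model-selection replicate experiment in the test suite is scaled to
  10 replicates of n = 2,000 for runtime; the selection margin at this size
  is already decisive (≈ 30 AIC points over the nearest family).
- No background all-cause mortality floor is added; no vial-sharing,
  societal costs, insurance splits, EVPI, or spline/cure survival models.
- The HR-as-exponent convention is a modelling commitment, not a claim
  about proportional hazards; results for comparator arms inherit its
  assumptions.
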