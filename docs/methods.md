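# Methods

This note documents the model, its numerical choices, and what the
synthetic data generator does and does not emulate.

## Model structure

The evaluation compares two strategies over a cohort entering in the
progression-free (PFS) state: daily oral osimertinib (80 mg) versus
platinum–pemetrexed chemotherapy (cisplatin 75 mg/m² for at most four
3-week cycles plus pemetrexed 500 mg/m² continued as maintenance until
progression). Three health states are modelled — progression-free,
progressed disease (PD), dead — with occupancy read directly off the
fitted PFS and OS curves (partitioned survival):

    pfs(t) = S_PFS(t)
    dead(t) = 1 − S_OS(t)
    pd(t)  = max(0, S_OS(t) − S_PFS(t))

Where extrapolated curves cross (S_PFS > S_OS), PD is clamped at zero,
PFS is capped at S_OS so occupancies still sum to one, and the number of
clamped cycles is reported on the trace. A per-cycle Markov-transition
mode built from conditional cycle probabilities is provided as a
cross-check; the two constructions agree exactly when the curves do not
cross. Whether the original spreadsheet/TreeAge-style model used state
membership or per-cycle transitions is not recoverable from the text;
partitioned survival is the default here because the transition
probabilities are stated to be derived directly from the two KM curves.

Cycle length is 21 days (21/365.25 years). The lifetime horizon is
operationalized as the earlier of 20 years or cohort survival falling
below 0.1%. Discounting of costs and outcomes uses the continuous-time
factor (1+r)^(−t) evaluated at mid-cycle, with r = 3%/year (US) or
5%/year (China). Half-cycle correction is the trapezoid rule: each
cycle's occupancy is the average of its boundary memberships. One-off
values (end-of-life cost) attach to the per-cycle increment of the dead
state; entry one-offs (mutation testing, expected adverse-event burden)
are applied undiscounted at time zero.

## Survival distributions and fitting

Four families are parameterized on the month scale:

| family | parameters | survival |
|---|---|---|
| exponential | rate λ | exp(−λt) |
| Weibull | scale λ, shape γ | exp(−λ t^γ) |
| log-logistic | scale α, shape β | 1/(1+(t/α)^β) |
| lognormal | μ, σ | 1 − Φ((ln t − μ)/σ) |

The log-logistic scale α is the median; the published analysis never
states its parameterization, so helpers (`median_survival`,
`mean_survival`) document the conversions. Fitting maximizes the
right-censored log-likelihood. The exponential rate has the closed form
(events)/(total follow-up). Two-parameter families are optimized by
Nelder–Mead on log-transformed positive parameters (lognormal μ
unconstrained) from three fixed moment-based starting points with a
final polish at tolerance 1e−10, which makes fits deterministic.
Model selection ranks by AIC (default) or BIC, with ties broken by
fewer parameters and then the fixed family order exponential → Weibull
→ log-logistic → lognormal. AIC is the default; the published analysis
combined information criteria with clinical judgement, which is not
operationalizable, so the criterion choice is exposed in configuration.

**Selection consistency limit.** Distinguishing log-logistic from
lognormal data is a logistic-vs-normal test on log-time and is
invariant to both parameters of the generating distribution; at n=300
uncensored observations the generating log-logistic family wins the
information-criterion contest in only ≈86% of replicates (measured over
300 simulations, with fits cross-checked against an independent MLE
implementation). No parameter choice moves this; only larger n does.
The exponential, Weibull and lognormal families are recovered in well
over 90% of replicates at the same size.

## Hazard-ratio adjustment and subgroups

Subgroups (and the CNS-metastases population) are modelled by keeping
every input at its base-case value except the PFS and OS hazard ratios:
the comparator keeps its fitted curves and the intervention curve is
S_ref(t)^HR (proportional hazards), the default because it is a valid
survival transform for any HR > 0. The literal reading of the source —
multiplying the survival *rate* by the HR — is retained as a
`rate_multiply` mode with clamping into [0,1], for replication only.
For the CNS population the comparator OS curve is shared with the ITT
comparator (the stated assumption in the absence of CNS OS curves).
Note that under this mechanism the CNS incremental QALY comes out
positive — the large PFS benefit (HR 0.32) outweighs the modest OS harm
(HR 1.19) — whereas the published table reports a small negative value
that depends on separately fitted CNS PFS curves and supplementary
inputs not available here.

## Pseudo-IPD reconstruction

Within each numbers-at-risk interval, each digitized survival drop from
S_prev to S contributes r·(1 − S/S_prev) events, where r is the
interval's starting risk count minus events already allocated in the
interval; censoring is treated as effective at the interval end for
this conversion, and the integer shortfall between the at-risk decline
and the rounded events is the interval's censor count. Event counts are
rounded by largest remainder so conservation is exact:
n₀ = Σevents + Σcensored + remaining-at-curve-end, on every input.
Expansion places events at their drop times and spreads an interval's c
censored records at equal spacing a + k(b−a)/(c+1); everyone past the
last risk-table entry is censored administratively at the final
follow-up time. The whole module is deterministic — no seed exists
anywhere downstream of a digitized curve.

The round-trip property (simulate → digitize → reconstruct → KM) is
evaluated at the digitization grid times: between reading points the
deviation is bounded below by the reading resolution itself (a drop
occurring between two grid times can only be recovered at the later
one), which no reconstruction can remove. At the grid, the round trip
is accurate to ≈0.003 for n = 300 with a 0.25-month reading grid and
3-month risk tables.

## Costs, adverse events, utilities

Per-cycle PFS costs: drug acquisition (dose resolved via BSA for per-m²
rules — 1.79 m² US / 1.72 m² China — or body weight for per-kg — 70/65
kg), one infusion fee per intravenous administration, and a follow-up
cost. Toxicity-related discontinuation (7% osimertinib, 10%
chemotherapy) removes the drug-acquisition cost for that fraction from
the second cycle onward while the cohort fraction remains in PFS with
all other costs — the source states the rates but not the mechanism, so
the simplest cost-side reading is used. PD costs are the mixture
fraction·subsequent-therapy + (1−fraction)·BSC with fractions 53%/81%.
Adverse events are grade ≥3 toxicities whose between-arm incidence
differs by strictly more than 5 percentage points; their expected
management cost and QALY decrement (incidence × disutility × duration)
are applied once at model entry, the common convention where timing is
unstated. There is no vial-size rounding: pricing is exact per mg.

## Sensitivity analysis

One-way analysis re-evaluates the model at each parameter's bounds
(95% CI where available, else ±25% of base; the discount rate is varied
0–8%) and ranks by ICER span; if the incremental effect changes sign
across a bound the span falls back to incremental NMB at the WTP and
is flagged. Probabilistic analysis draws all parameters independently —
gamma for costs, beta for probabilities and utilities, normal for
hazard ratios, BSA and weight (truncated positive by redraw; a
log-normal option exists because a normal-scale HR can go negative) —
with moments matched to (base, se) where se = (high − low)/(2·1.96),
reading the range as a 95% interval (the divisor is configurable; the
source does not state how standard errors were obtained for ±25%
ranges). The discount rate is excluded from the probabilistic analysis
as a methodological rather than sampling uncertainty. The default is
10,000 Monte-Carlo iterations; tests and the acceptance script use
2,000 draws, which keeps Monte-Carlo error on acceptance probabilities
near one percentage point while running in seconds.

## Synthetic data generator

`survecon.simulate` emulates the two-arm trial the model consumes:
279 vs 140 patients; intervention PFS/OS log-logistic with medians
10.1/26.8 months (shapes 1.8/2.1, chosen so the 24- and 36-month OS
landmarks land near the published 55%/37%); comparator PFS/OS Weibull
with medians 4.4/22.5 months (shapes 1.25/1.4, matching the 43%/30%
landmarks); administrative censoring at 27 (PFS) and 48 (OS) months
plus a small random-censoring rate (0.005/month); risk tables every 3
months; digitization at 0.25-month steps with survival rounded to 3
decimals (plot-reading precision). It does **not** emulate patient
covariates, treatment switching, interval-censored reads, digitizer
bias, or real-world dose intensity — so passing tests demonstrate the
pipeline's internal consistency and parameter recovery under clean
trial-shaped data, not robustness to messy published figures. Emitted
unit costs, utilities and AE tables are synthetic stand-ins on
realistic scales (drug prices 6.62/0.36 $/mg, dosing rules, discount
rates and WTP thresholds follow the modelled setting) and are labeled
as such in the emitted files.

## Numerical conventions and edge cases

- Times are months at every interface; years appear only inside
  discounting (1 cycle = 21/365.25 years).
- Zero-length cycles give transition probability 0; an exhausted
  survival curve (S(t)=0) gives probability 1 with a warning.
- ICERs are reported as the raw ratio ΔC/ΔE without quadrant
  relabeling (a cheaper-and-less-effective strategy prints a positive
  ICER; a costlier-and-less-effective one prints a negative ICER); the
  dominance flag carries the interpretation, and ICER is undefined
  (None) at ΔE = 0 while NMB remains valid.
- The price-threshold search uses Brent's method on incremental NMB
  (monotone because total drug cost is linear in unit price) to a
  $0.001/mg tolerance.
- Utilities outside [0,1] warn rather than fail, since adverse-event
  disutilities can push an effective utility below a state's baseline.
- Configuration validation is strict (unknown keys are errors) and
  collects every problem before raising, naming each offending key.

## Known limitations

- No spline/cure models, time-varying hazard ratios, tunnel states, or
  microsimulation; no more-than-two-strategy frontiers, EVPI, or
  correlated PSA draws.
- The published base-case ICERs cannot be reproduced numerically: they
  depend on unrounded internal totals and supplementary parameter
  values (exact unit costs, utilities, AE lists, fitted survival
  parameters) that are not in the available text. The incremental
  identities of the published per-arm totals, and the qualitative
  structure (quadrants, dominance, tornado leader), are what the tests
  assert.
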