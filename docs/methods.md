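# Methods

## Decision problem and model structure

A patient with unresectable malignant distal biliary obstruction has failed
ERCP and requires salvage drainage: EUS-guided biliary drainage (EUS-BD) or
percutaneous transhepatic biliary drainage (PTBD, with subsequent outpatient
stent internalization). Because the two strategies have similar technical
and clinical success, the comparison is a **cost-minimization**: no
effectiveness dimension, no ICER/QALY.

Each strategy is a two-branch episode: the bundled initial reimbursement is
always incurred; with probability `p_s` one bundled unscheduled
re-intervention is added. The expected 30-day cost is the affine form

    E[C_s] = C_init,s + p_s · C_reint,s

Technical failures and minor adverse events are folded into the
re-intervention rate (double-counting avoidance), and deaths/serious adverse
events are assumed absent over the horizon. With a 30-day horizon and zero
discount rate the model collapses to this single decision episode — the
horizon and discount fields are carried for reporting but cannot change any
output. All printed base-case values are reproduced exactly by this closed
form, which is why the implementation is a collapsed decision tree rather
than an explicit state-transition (Markov) engine.

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `C_init` (EUS-BD / PTBD) | 8,002.48 / 13,369.98 | USD | Medicare initial-episode bundle |
| `C_reint` (EUS-BD / PTBD) | 6,351.83 / 957.11 | USD | Medicare re-intervention bundle |
| re-intervention counts | 8/34, 17/32 | — | binomial evidence (k events / n trials) |
| horizon | 30 | days | episode length; inert at discount 0 |
| PSA trials | 10,000 | — | Monte-Carlo sample size |
| CI level | 0.95 | — | empirical percentile interval |
| grid | [0, 0.5]², step 0.01 | — | deterministic sensitivity range |

Re-intervention rates are stored as **counts, not percentages**. The
published table prints rounded display rates (23.6%, 53.1%); only the exact
fractions 8/34 = 0.2353 and 17/32 = 0.53125 reproduce the published
expected costs to the cent. The source trial's denominators (8/32, 17/31,
i.e. technical successes) are retained as the *Korean* arm defaults; the US
model's 8/34 / 17/32 are kept because they are the only counts consistent
with the published base case. Both are user-configurable.

Money is validated and stored as exact decimals (cent precision) at the I/O
boundary; model arithmetic uses IEEE doubles (relative error ~1e-12 on
dollar scales), and half-up rounding to cents happens only at presentation.

## Probabilistic sensitivity analysis

Each strategy's probability is `Beta(α, β)` with the **counts rule**
α = k, β = n − k, whose mean k/n equals the base-case point estimate, so the
PSA mean converges to the base-case cost. A Jeffreys option
(α = k + ½, β = n − k + ½) is provided for zero-event evidence, where the
counts rule is undefined. The two strategies are sampled independently
(no correlation evidence exists). Intervals are empirical percentile
intervals (linear-interpolation quantiles); the published interval's
asymmetry around the EUS-BD mean is consistent with percentile rather than
normal-theory intervals.

Numerical detail: since cost is a monotone affine map of `p`, interval
endpoints are computed as `C_init + q·C_reint` with `q` the percentile of
the probability sample. This is mathematically identical to taking
percentiles of the cost sample and, unlike that route, is exactly
reproducible from the probability stream (the order of multiply/add in
interpolation otherwise perturbs the last floating-point bits). Per-strategy
streams are spawned from a single `SeedSequence(seed)`, so every report is
reproducible from its seed.

## Deterministic sensitivity

The preference surface evaluates the closed form on a (p_EUS, p_PTBD) grid
(default step 0.01 on [0, 0.5]²; results are step-independent because both
costs are affine). Strict preference requires a cost gap above one cent;
smaller gaps are ties. The one-way analyses are the two axis-aligned slices
holding the other strategy at its base-case rate. The cost-equivalence
threshold and the largest square [0, b]² on which EUS-BD stays strictly
preferred have closed forms; with the default inputs b ≈ 0.845
(worst case: PTBD at p = 0).

## Trial-level comparison

Per-patient records carry hospital charges other than drainage, primary
drainage cost, re-intervention cost and counts; drainage total and grand
total are derived sums. Arms are summarised as median (min–max); medians of
sums deliberately do not equal sums of medians.

*Mann-Whitney*: exact enumeration path when the smaller sample has ≤ 8
observations and the pooled sample is tie-free; otherwise the normal
approximation with tie-corrected variance and continuity correction
(delegated to `scipy.stats.mannwhitneyu`; an independent brute-force
enumeration oracle lives in the test suite). The result object records
which path ran. α = 0.05 two-sided, no multiplicity adjustment —
per-category p-values are reported as-is.

*Bootstrap*: the statistic is the difference in arm means (a median option
exists); the published difference table is consistent with means, not
medians. Resampling is stratified within arm with replacement, preserving
arm sizes (two-sample design). The interval is **bias-corrected (BC)**
percentile: z0 = Φ⁻¹(fraction of bootstrap statistics below the observed
statistic) shifts the percentile levels to Φ(2z0 ± z_{α/2}); BCa (jackknife
acceleration over both arms) is available as an option. At z0 = 0 the BC
interval equals the plain percentile interval; endpoints are (interpolated)
order statistics of the bootstrap sample and never extrapolate beyond its
range. Degenerate resamples (all statistics identical) collapse the
interval and are flagged. The phrase-level description of the original
bootstrap procedure mentions stepwise variable selection; no covariates or
selection rule are specified anywhere, so this package implements the
stated deliverable — the BC interval for the between-arm cost difference —
and exposes the statistic choice in configuration.

## Synthetic trial generator

The raw per-patient trial data are not deposited, so the generator is the
test bed for the trial-level machinery. It emulates:

- arm sizes 34 (EUS-BD) / 32 (PTBD);
- Bernoulli re-intervention with rates 8/32 and 17/31, then a
  zero-truncated Poisson event count whose conditional means (11/8, 29/17)
  reproduce the published mean frequencies 0.34 and 0.93 per patient;
- per-event re-intervention costs, and per-patient hospital and primary
  drainage costs, from truncated log-normal distributions (right-skewed
  positive costs, consistent with median ≪ max in the published summaries);
- session structure: every EUS-BD drainage is single-session; 15/31 of
  percutaneous drainages need 2 or 3 sessions (the published count does not
  split 2 vs 3; the generator splits evenly), the rest remain single-session
  external drains.

**Calibration** maps each published median (min–max) to a distribution by
log-scale moment matching: location = log median; scale = printed log-range
divided by d2(n), the expected range of n standard-normal draws (the
printed extremes are the realised range of an arm-sized sample); then hard
truncation to the printed range. Component medians do not add, so a final
recentering pass simulates replicate arms of the configured size and shifts
the hospital-charge location until the median of simulated arm medians of
the grand total matches the published total (the published total median is
itself an arm-sized sample statistic). The re-intervention category's
published summary includes zero-cost (event-free) patients; its calibrated
distribution is interpreted on the per-event cost scale with a
log-symmetric lower bound, which is the main reason per-category
reproduction of the re-intervention row is approximate.

What the generator does **not** emulate: correlation between cost
components within a patient (defaults to independence; the dependence
structure of the real data is unknown), length-of-stay as an explicit
variable, adverse-event types, or any clinical endpoints. Passing tests
therefore demonstrate that the statistical machinery is correct and that
the generator matches the published summary structure — not that it
reproduces the unavailable raw data.

Problem sizes used by the test suite: 10,000 Monte-Carlo trials per PSA run
repeated over 20 seeds; 200 seeded synthetic trials for the calibration
check; 500 replicates × 1,000 resamples for bootstrap coverage; exhaustive
rank-split enumeration up to pooled n = 10 for the Mann-Whitney oracle.

## Numerical and degenerate-input choices

- Quantiles: linear interpolation everywhere (numpy default), documented
  and frozen in tests.
- Ties in the decision model: cost gaps below $0.01 are reported as ties;
  the CLI labels neither strategy preferred.
- `Beta(k, n−k)` rejects k = 0 or k = n with a message pointing to the
  Jeffreys rule.
- Zero re-intervention cost makes the PSA interval collapse to the initial
  cost and the equal-cost threshold undefined (no crossing) unless the
  fixed costs already tie.
- The bootstrap refuses arms with fewer than 2 patients; constant arms
  return a flagged degenerate interval.
- Generator determinism: one `numpy.random.default_rng(seed)` consumed in a
  documented order (hospital, primary/sessions, event indicators, counts,
  unit costs; first arm then second); identical seed and config give
  byte-identical CSV output.

## Known limitations

- The calibration criterion for the PTBD arm is intrinsically tight: the
  spread implied by the published hospital-charge range makes the
  32-patient total-cost median fall within ±15% of its target in only
  ~91% of runs; small changes to the generating law would move this a few
  percentage points either way.
- The US model treats bundle costs as fixed reimbursements (no cost
  distributions), matching the published analysis; real claims vary.
- Mean-difference bootstrap intervals on n ≈ 33 skewed samples undercover
  slightly relative to nominal (observed ~92–93% at nominal 95%), a known
  property of BC intervals at these sample sizes.
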