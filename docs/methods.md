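# Methods

## Decision problem

A cohort of 30-year-olds with suspected neuroendocrine tumor (pre-test
probability 0.05) undergoes one imaging strategy — CT alone (sensitivity
0.77, specificity 0.86, \$787), ¹¹¹In-pentetreotide SPECT/CT (0.70/0.96,
\$1,242) or ⁶⁸Ga-DOTA-TATE PET/CT (0.91/0.92, \$1,375). The diagnostic
result fixes the entry conditions of a lifetime Markov cohort model; the
strategies are then ranked by expected discounted lifetime cost and QALYs.

## Decision tree

Branch probabilities follow directly from prevalence and test accuracy
(p·sens, p·(1−sens), (1−p)·spec, (1−p)·(1−spec)). Acute costs at entry:

| outcome | acute cost | Markov entry |
|---|---|---|
| TP | imaging + biopsy (\$1,375) + timely surgery/treatment (\$85,068) | clinically relevant, treated, timely track |
| FN | imaging + delayed surgery/treatment (\$127,602) | clinically relevant, untreated |
| TN | imaging | no relevant burden |
| FP | imaging + unnecessary biopsy (\$1,375) | no relevant burden, post-workup reward track |

The confirmatory biopsy is charged to *every* test positive — the source
tariff lists it once as a standalone workup cost and once as the
false-positive "unnecessary biopsy" — because a positive scan is always
biopsied before surgery. This is the clinically coherent reading and it is
toggleable (`charge_biopsy_to_test_positives: false`).

## Markov model

Six states, 1-year cycles, from age 30 to the horizon age 100 (70 cycles);
remaining survivors at the horizon are truncated without terminal reward.

| state | yearly cost | utility |
|---|---|---|
| no relevant burden | \$0 | 1.0 (0.779 in an FP cohort's first cycle) |
| post-treatment remission | \$2,107 | 0.779 |
| clinically relevant, untreated | \$61,375 | 0.612 |
| clinically relevant, treated (timely or delayed) | \$61,375 | 0.768 |
| death | \$0 | 0 |

Transitions, conditional on survival: untreated disease is always detected
and treated after one year (delayed track); treated disease moves to
remission after the treatment year; disease-free states (including
remission) progress/recur into treated disease at 8.8 %/yr. Death combines
the state's disease-specific risk (timely 4.0 %, delayed 4.5 %, untreated
12.12 %, none when disease-free), the 2.5 %/yr competing-cause risk and the
age-specific life-table probability (times a relative-risk multiplier,
default 1) as independent competing risks:
`p_die = 1 − (1−p_disease)(1−p_competing)(1−q_age·rr)`.

Structural judgment calls, each isolated behind a single function so
alternatives can be swapped:

* **Remission tunnel.** Treated survivors spend exactly one cycle in the
  expensive treated state, then carry the \$2,107/0.779 remission profile
  and can recur. This wires every published parameter into the model
  exactly once; the authors' original tool file is not public, so this is
  the main reconstruction choice.
* **Delayed-track memory.** The only individual-level memory is the
  timely/delayed tag during the treated cycle (4.0 % vs 4.5 % death);
  recurrences from remission re-enter on the timely track, since recurrent
  disease is detected under surveillance.
* **Post-workup reward track.** An FP cohort's first cycle is rewarded at
  0.779 instead of 1, reflecting the morbidity of the unnecessary workup;
  afterwards it is indistinguishable from a TN cohort (they share the
  state — a lifelong utility decrement for a healthy false positive would
  be implausible).
* **Untreated utility.** The source utility set also lists 0.690 "without
  treatment"; the one-cycle calibration (0.612 QALYs for a false-negative
  cohort after one year) identifies 0.612 — the disease-progression
  utility — as the untreated-state reward, so 0.690 is stored but unused.

## Reward timing and discounting

Rewards are credited to the state occupied at the *start* of each cycle; no
half-cycle correction; cycle *k* is discounted by (1+r)^−(k−1) with r=0.03,
so the first cycle is undiscounted. These conventions are forced by exact
one-cycle identities of the published model: TP cost after one year
85,068 + 61,375 = 146,443.00 to the cent, and first-cycle QALYs equal to
the raw state utility (0.768 / 0.612 / 0.779 / 1.0). Acute costs enter
undiscounted in cycle 1.

## Life table

Background mortality comes from a two-column (age, qx) CSV. The bundled
table is *synthetic*: a Gompertz–Makeham curve qx = min(1, a + b·e^(c·age))
with a = 5×10⁻⁴, b = 3×10⁻⁵, c = 0.09, terminal qx(100) = 1, whose adult
values sit in the plausible range of a recent US period life table
(≈9×10⁻⁴ at 30, ≈0.04 at 80). It approximates the shape, not any
published vintage; runs against a real national table will differ in the
third decimal of lifetime QALYs. Ages are integers and never interpolated
(the cycle length is one year); no sex stratification.

## Cost-effectiveness analysis

ICER = (C₁−C₀)/(E₁−E₀). A cheaper-and-more-effective strategy is flagged
*dominant* and no ratio is reported (signed negative ratios are ambiguous).
The efficiency frontier sorts by cost (ties broken by higher effect),
removes strictly dominated options, and removes extended-dominated options
until sequential ICERs strictly increase. NMB = λ·E − C; the NMB maximizer
at a willingness-to-pay λ is the cost-effective choice (λ = \$100,000/QALY
by default).

## Sensitivity analysis

**Deterministic.** One-way sweeps re-run the entire pipeline at the low and
high end of a parameter's range with everything else at base values and
record the incremental NMB of PET/CT against the best comparator. The
published analysis states only that ranges were "in the range of the
assumed baseline values"; the default here is ±20 % of the base value,
clipped to the parameter's domain, and configurable (`dsa_fraction`). The
default sweep set is the ten diagnostic parameters (six accuracies, three
imaging costs, biopsy cost). Note that ±20 % is a *wide* range for a
specificity: sweeping PET/CT's specificity to 0.736 creates so many
false-positive workups (each costing the biopsy plus a first-year utility
decrement of 0.221) that no Table-level parameterization keeps PET/CT
cost-effective there — robustness claims are meaningful only for narrower,
evidence-based accuracy ranges.

**Probabilistic.** The published inputs assign beta distributions to
probabilities/utilities and gamma distributions to costs but no spreads.
Spreads are therefore second-order defaults in common CEA practice,
overridable per parameter: beta parameters are moment-matched with an
effective sample size (α = m·s, β = (1−m)·s, default s = 100) and gamma
parameters with a coefficient of variation (shape = 1/cv², scale = m·cv²,
default cv = 0.2). Parameters whose mean sits on the boundary of the
family's support (utility 1, cost 0, transition probability 1) are point
masses. Draws are independent across parameters (no correlation structure
is published), one seeded generator per run, 30,000 iterations by default,
evaluated by a vectorized cohort engine (~1 s for 30,000 draws × 3
strategies). Acceptability curves report, per WTP grid point, the fraction
of draws in which each strategy attains the strictly highest NMB, ties
split equally. At λ = 0 the contest degenerates to "cheapest strategy";
because PET/CT's base-case cost advantage (≈\$13) is far below the
between-draw noise in cost differences, its acceptability there is ≈0.46 —
an intrinsic feature of any nondegenerate parameterization of this model,
not an artifact of the spreads chosen.

## Validation strategy

* **Calibration identities** (exact): the one-cycle outcomes above pin the
  reward timing, discount indexing and parameter wiring.
* **Microsimulation oracle**: an individual-level simulator replays the
  same transition matrices and rewards on 200,000 independent trajectories;
  cohort expectations must agree within 3 Monte Carlo standard errors
  across 10 randomized configurations × all four entry conditions. The
  oracle shares the transition/reward code deliberately — it validates the
  expectation algebra (matrix propagation, discounting), while the wiring
  is validated separately by the calibration identities. Randomized
  configurations use moderate horizons (ages ~55–75) to keep the check
  fast; the algebra being validated is horizon-independent.
* **Closed-form limits**: zero mortality + unit utilities + zero discount
  gives QALYs exactly equal to the cycle count; at zero prevalence the
  strategies differ only by imaging cost and the false-positive workup
  (cost and first-cycle utility) terms.
* **Engine cross-check**: the vectorized PSA engine at point-mass spreads
  reproduces the trace-based scalar engine.

## What the synthetic data do and do not show

The generator produces valid configurations and a US-shaped mortality
curve; passing tests demonstrate internal correctness of the pipeline
(probability algebra, reward accounting, dominance logic, Monte Carlo
machinery) under the published study conditions. They do not validate the
clinical inputs themselves, the transferability of 2020 Medicare tariffs,
or the published model's own absolute lifetime totals, which are not
derivable from its printed inputs (see Limitations).

## Limitations

* The original model structure is not published; this reconstruction
  reproduces the one-cycle outcomes exactly and the qualitative lifetime
  result (PET/CT strictly dominant; CT ahead of SPECT/CT on cost), but its
  absolute lifetime totals (~\$104k, ~14.3 QALYs per strategy) differ from
  the published totals (~\$88–90k, ~4.17 QALYs), which imply an effective
  discounted survival of only ≈5 years — unreachable from the printed
  transition inputs, under which the 95 % disease-free majority faces only
  2.5 %/yr competing plus background mortality. The published TN/FP
  one-year cumulative costs (\$23,979/\$34,208) are likewise not
  decomposable from the printed \$0 acute and \$0 yearly disease-free
  costs. Comparisons between strategies (the decision-relevant quantity)
  are far more robust to this than the absolute levels.
* Disease is binary ("clinically relevant" or not): no tumor grade, stage
  or site heterogeneity, no imperfect reference standard for the biopsy.
* No currency-year adjustment or non-US tariffs; no EVPI/EVPPI.
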