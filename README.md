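# netcea

Decision-analytic cost-effectiveness modelling of diagnostic imaging
strategies for neuroendocrine tumors (NETs): CT alone, ¹¹¹In-pentetreotide
SPECT/CT and ⁶⁸Ga-DOTA-TATE PET/CT.

Most NETs express somatostatin receptors, so receptor-targeted nuclear
imaging (SPECT/CT, and especially ⁶⁸Ga-DOTA-TATE PET/CT) detects them with
higher sensitivity than CT — at a higher acute price. Whether the extra
imaging cost pays for itself through earlier, cheaper, more effective
treatment is a health-economics question. `netcea` answers it with the
standard machinery of model-based health technology assessment, built for
US-system costs (2020 USD):

* a **diagnostic decision tree** that splits an imaged cohort (pre-test
  probability *p* = 0.05) into TP/FP/TN/FN branches from each test's
  sensitivity and specificity, with branch-specific acute costs (imaging,
  confirmatory biopsy, timely vs delayed surgery + treatment);
* a **lifetime Markov cohort model** (annual cycles, age 30 → 100) over the
  states *no relevant tumor burden*, *clinically relevant tumor burden
  without treatment*, *clinically relevant tumor burden with treatment*
  (timely/delayed tracks), *post-treatment remission* and *death*, with
  disease-specific, competing-cause (2.5 %/yr) and life-table background
  mortality combined as independent risks, and state rewards in dollars and
  utilities (QALY weights) discounted at 3 %/yr;
* **cost-effectiveness comparison** by incremental cost-effectiveness ratio
  ICER = (C₁−C₀)/(E₁−E₀), dominance flags, the efficiency frontier and net
  monetary benefit NMB = λ·E − C at a willingness-to-pay λ = \$100,000/QALY;
* **deterministic sensitivity analysis** (one-way ±20 % sweeps, tornado
  table of incremental NMB) and **probabilistic sensitivity analysis**
  (30,000 Monte Carlo draws from moment-matched beta/gamma distributions,
  cost-effectiveness acceptability curves over λ ∈ [0, \$200,000]);
* a **microsimulation oracle** and randomized-configuration generator that
  validate the cohort algebra against individual-level simulation.

The intended users are health-economics/HTA analysts and methods
researchers who want a scriptable, tested, fully parameterized version of
this class of diagnostic-workup CEA.

## Worked example

```python
from netcea import DecisionModel

model = DecisionModel()        # published base case, bundled life table
results = model.run()
print(results.summary())
```

prints

```
Cost-effectiveness analysis (WTP $100,000/QALY, discount 3.0%, ages 30-100)

strategy          cost ($)    QALYs     Δcost ($)   ΔQALYs  ICER / status
CT              103,764.70   14.282         13.04   -0.024  dominated
SPECT/CT        104,350.41   14.298        598.75   -0.008  dominated
PET/CT          103,751.67   14.306          0.00    0.000  (comparator)

efficiency frontier: PET/CT
```

Read: over a lifetime horizon the PET/CT strategy is simultaneously the
cheapest (its higher imaging cost is more than repaid by fewer delayed
treatments and fewer unnecessary biopsies) and the most effective (fewest
false negatives spending a year untreated at utility 0.612), so it strictly
dominates both comparators and is the only strategy on the efficiency
frontier — no ICER needs to be paid for it. The one-cycle outcomes behind
these totals are exact arithmetic identities of the inputs: a true-positive
cohort has accrued \$85,068 + \$61,375 = \$146,443.00 on the treatment path
and 0.768 QALYs after its first (undiscounted) year; a false-negative
cohort \$127,602 + \$61,375 = \$188,977.00 and 0.612 QALYs.

Uncertainty analyses hang off the same object:

```python
samples = model.psa()                    # 30,000 seeded draws, ~1 s
from netcea import ceac
curve = ceac(samples, range(0, 200_001, 5_000))
print(float(curve.loc[curve.wtp == 100_000, "PET/CT"].iloc[0]))  # 0.8087
tornado = model.tornado()                # one-way ±20% sweeps
```

At \$100,000/QALY, PET/CT has the highest net monetary benefit in 80.9 % of
draws. The tornado table shows the decision is most sensitive to PET/CT's
own specificity and sensitivity: pushing either 20 % below its base value
flips the incremental NMB negative, while every cost parameter sweep leaves
PET/CT cost-effective.

The same analyses are available from a shell:

```bash
netcea basecase --out results/base
netcea dsa      --out results/dsa  --plots
netcea psa      --out results/psa  -n 30000 --seed 1 --plots
```

Each command writes CSV outputs plus a JSON run manifest; partial YAML
configs merged over the defaults are accepted via `--config` (schema in
`src/netcea/data/config.schema.json`).

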