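# rdrtb

Multiple imputation for missing longitudinal trial endpoints under the
treatment-policy estimand, combining **retrieved-dropout (RD)** imputation
with a weighted **return-to-baseline (RTB)** correction — the hybrid
**RD-RTB** method — plus the plain RD and RTB methods, an ANCOVA /
Rubin's-rules estimation pipeline, and a clinical-trial simulator for
benchmarking all three against a known truth.

## The problem

In long-term randomized trials, subjects who stop treatment after an
intercurrent event (adverse reaction, lack of efficacy, rescue medication)
often stop contributing outcome data, leaving missing-not-at-random (MNAR)
endpoints. Two common single-assumption repairs sit at opposite extremes:

* **RTB** assumes the treatment effect vanishes after discontinuation:
  imputed final-visit values are re-centered so their mean returns to the
  baseline mean, `Y_iJ* = Y_iJ(imp) − Ȳ_J + Ȳ_0` — conservative, and
  increasingly biased as real retained efficacy grows.
* **RD** imputes the dropouts from *retrieved dropouts* — subjects who
  discontinued treatment but stayed in the trial — assuming non-retrieved
  dropouts behave like retrieved ones, which fails when their intercurrent
  events differ.

**RD-RTB** starts from the RD imputation and adds a per-subject correction

    α_i = sign(ρ) · |1 − φ0/φ1| · w_i · β,      w_i = exp(−(Y_i0 − min Y_0) · t_i / T)

where `β = Ȳ_0 − Ȳ_J(imp)` is the full RTB correction for the arm's imputed
subjects, `w_i` shrinks it by baseline severity and exposure time `t_i`
relative to the planned duration `T`, `ρ = V_rd − V_mis` compares the
pre-withdrawal efficacy rates (points/week of signed change from baseline)
of retrieved vs non-retrieved dropouts, and `φ0/φ1` compares withdrawers'
imputed |change| with completers' observed |change|. The arm with the larger
mean |α| (the γ arm) additionally pulls each subject's correction toward
that mean with weight `1 − w_i`. Imputed final-visit values become
`Y_iJ(imp) + α_i` (δ arm) or `Y_iJ(imp) + α_i + (1 − w_i)(γ − α_i)` (γ arm).
Each completed dataset is analysed by ANCOVA (change from baseline at the
final visit on arm + baseline, least-squares means at the grand-mean
baseline) and the M results combined with Rubin's rules.

The simulator emulates an 8-week antidepressant trial with biweekly HAMD-17
scores (total score 0–52, lower is better): baseline ~ N(25, 5) truncated to
[15, 35], mean decline 2.5 points/visit (treatment) vs 0.5 (placebo), visit
noise SD 0.5, 400 subjects/arm, 30 % treatment withdrawal split 1:1:1 over
visits 2–4, 20 % of withdrawers retrieved. Withdrawers keep a configurable
fraction of their pre-withdrawal change (10–150 %); placebo withdrawers
receive rescue medication worth 150 % of theirs. Four scenarios flip whether
withdrawers beat completers and whether non-retrieved dropouts beat
retrieved ones before withdrawal.

## Worked example

```python
import numpy as np
from rdrtb import (SimConfig, simulate_trial, rd_rtb_impute, pool_draws,
                   true_effect)
from rdrtb.mi import ImputationModelSpec

cfg = SimConfig(scenario=1, retained_weight_trt=0.1)
truth, observed = simulate_trial(cfg, rng=np.random.default_rng(42))
print("true effect:", round(true_effect(truth), 4))

spec = ImputationModelSpec(donor_rule="rd_only", n_imputations=50)
draws, ledger = rd_rtb_impute(observed, spec, np.random.default_rng(7),
                              return_ledger=True)
pooled, estimates, ses = pool_draws(draws)
print("RD-RTB pooled estimate:", round(pooled.estimate, 4))
print("Rubin SE:", round(pooled.se, 4), " mean LSM SE:", round(float(ses.mean()), 4))
print("gamma arm:", ledger.gamma_arm, " gamma:", round(ledger.gamma, 4))
```

prints

```
true effect: -4.9911
RD-RTB pooled estimate: -5.0493
Rubin SE: 0.2522  mean LSM SE: 0.2354
gamma arm: treatment  gamma: 0.0406
```

The true treatment effect of this simulated trial — the ANCOVA arm contrast
on the fully observed counterfactual data — is −4.99 HAMD-17 points
(treatment lowers the score ~5 points more than placebo once 30 % of the
treatment arm withdraws and keeps only 10 % of its gains). The RD-RTB
pooled estimate lands within 0.06 points of it; the Rubin SE (0.252)
combines the mean per-imputation ANCOVA SE (0.235) with between-imputation
spread. The ledger records every correction quantity (β, w_i, rates, sign,
φ scale, γ/δ) per arm.

A command-line interface mirrors the library:

```bash
rdrtb simulate --config cfg.yaml --seed 1 --out data/
rdrtb impute --method rd_rtb --in data/observed.csv --m 100 --seed 2 --out draws/
rdrtb analyze --in draws/ --out result.json
rdrtb evaluate --scenario 1 --datasets 100 --imputations 100 --seed 3 --out eval/
```

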