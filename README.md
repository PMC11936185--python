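# psmcea

A partitioned-survival cost-effectiveness model for first-line
**tislelizumab + platinum/etoposide versus platinum/etoposide alone** in
extensive-stage small cell lung cancer (ES-SCLC), from the Chinese
healthcare-system perspective.

The package is aimed at health economists and methods researchers who want
a fully scripted, testable re-implementation of this published decision
model: every stage — parametric survival extrapolation, cohort trace,
cost/QALY accrual, incremental economics, one-way and probabilistic
sensitivity analysis — is an importable, unit-tested function, and a
synthetic-data module generates trial-like survival data with known ground
truth so the whole pipeline runs with no external download.

## The model

Three mutually exclusive health states — progression-free (PF),
progressed-alive (PD), dead — are occupied directly from the
progression-free survival and overall survival curves (a *partitioned
survival model*, no transition matrix):

```
PF(t)   = min(S_PFS(t), S_OS(t))
PD(t)   = S_OS(t) − PF(t)
dead(t) = 1 − S_OS(t)
```

Survival is extrapolated with log-logistic distributions,
`S(t) = 1 / (1 + λ t^γ)` (time in months), with arm-specific (γ, λ) fitted
from digitized Kaplan–Meier coordinates of the RATIONALE-312 trial via
pseudo-data reconstruction and interval-censored maximum likelihood
(six candidate families, minimum-AIC selection with BIC tie-break).

The cohort is traced over 174 cycles of 21 days (10-year horizon), costs
and QALYs discounted at 5 %/year.  Costs cover drug acquisition (BSA-dosed
etoposide, Calvert-dosed carboplatin or BSA-dosed cisplatin with a 50/50
split, flat-dose 200 mg tislelizumab with maintenance until progression),
grade ≥3 adverse events, monitoring, one-time subsequent therapy at
progression, and best supportive care in PD.  The decision metric is the
incremental cost-effectiveness ratio (ICER = Δcost/ΔQALY) against a
willingness-to-pay threshold of $39,855.79/QALY (3× 2023 Chinese
per-capita GDP), equivalently the net monetary benefit
NMB = WTP·ΔQALY − Δcost.

## Worked example

```python
from psmcea import load_parameters, run_base_case

deck = load_parameters()          # the shipped base-case parameter deck
res = run_base_case(deck)
print(f"tislelizumab arm:  ${res.intervention.total_cost:,.2f}, "
      f"{res.intervention.total_qalys:.4f} QALYs")
print(f"chemotherapy arm:  ${res.comparator.total_cost:,.2f}, "
      f"{res.comparator.total_qalys:.4f} QALYs")
print(f"ICER: ${res.icer:,.2f}/QALY  (cost-effective: {res.cost_effective})")
```

prints

```
tislelizumab arm:  $17,205.41, 1.0461 QALYs
chemotherapy arm:  $10,570.85, 0.7788 QALYs
ICER: $24,821.68/QALY  (cost-effective: True)
```

Adding tislelizumab costs an extra $6,634.56 and gains 0.2673 discounted
QALYs; at $24,822 per QALY gained this is below the $39,855.79 threshold,
so the combination is cost-effective under this model — the same decision
as the source analysis (see `docs/methods.md` for a detailed comparison
with the published totals, which this model does not reproduce in absolute
terms).

The same run, plus tornado and probabilistic sensitivity analyses with
CSV/plot outputs and a run manifest, is available from the shell:

```bash
psmcea run --out results/ --seed 42 --plots
psmcea owsa --out tornado.csv
psmcea psa --iterations 10000 --seed 42 --out psa.csv
psmcea simulate --family loglogistic --shape 1.92 --scale 0.035 \
    --n 230 --censor 36 --out curve.csv
psmcea fit --curve curve.csv --family all --cohort-size 230 --out fits.csv
```

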