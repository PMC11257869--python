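# escea

Cost-effectiveness modelling of first-line immunochemotherapy for
extensive-stage small-cell lung cancer (ES-SCLC), from the perspective of
the Chinese healthcare system.

Standard first-line treatment for ES-SCLC is platinum–etoposide
chemotherapy; adding an immune checkpoint inhibitor (ICI — atezolizumab,
durvalumab ± tremelimumab, serplulimab or adebrelimab) extends survival at
substantial drug cost. `escea` is a reusable, tested decision-modelling
pipeline for asking whether that trade-off is worth paying for:

1. **Pseudo-IPD reconstruction** (`escea.ipd`) — invert digitized
   Kaplan–Meier coordinates plus number-at-risk tables into patient-level
   event/censor times (interval-wise product-limit inversion).
2. **Parametric survival** (`escea.survival`) — censored maximum-likelihood
   fits for six families with AIC/BIC selection. The working
   parameterisation is log-logistic,
   `S(t) = 1 / (1 + exp(θ) t^κ)`,
   and comparator arms apply a hazard ratio as an exponent,
   `S_ICI(t) = S(t)^HR`.
3. **Cohort model** (`escea.markov`) — three states (progression-free
   disease, progressed disease, death), 21-day cycles, 20-year horizon
   (348 cycles), occupancy partitioned from the PFS and OS curves.
4. **Economics** (`escea.economics`) — anthropometric drug dosing
   (per-kg, per-BSA, Calvert `AUC × (CrCl + 25)`, flat), one-off grade 3/4
   adverse-event costs and disutilities, per-cycle follow-up / best
   supportive care / subsequent therapy, palliative care at death; costs
   and QALYs discounted at 5%/year.
5. **Frontier** (`escea.frontier`) — pairwise and stepwise incremental
   cost-effectiveness ratios (ICER = ΔCost/ΔQALY), strict and extended
   dominance, net monetary benefit.
6. **Sensitivity** (`escea.sensitivity`) — one-way DSA with tornado
   ranking, bisection threshold search, probabilistic sensitivity analysis
   (10,000 Monte Carlo draws by default) and cost-effectiveness
   acceptability curves.
7. **Synthetic data** (`escea.synthetic`) — seeded cohort simulators, a
   digitizer stand-in, the published strategy-level (cost, QALY) table and
   a complete synthetic demonstration workbook.

## Worked example

```python
from escea.synthetic import demo_workbook
from escea.pipeline import run_base_case
from escea.frontier import frontier, icer

results = run_base_case(demo_workbook())
chemo = results[0]
for r in results:
    print(f"{r.strategy:40s} {r.total_cost:12,.2f} {r.total_qalys:.5f}")
print(frontier(results).frontier_strategies)
```

prints (synthetic inputs, USD and discounted QALYs per patient):

```
chemotherapy                                22,990.22 1.33209
serplulimab+chemotherapy                    97,735.33 2.33875
adebrelimab+chemotherapy                    60,226.39 1.97212
atezolizumab+chemotherapy                   93,016.52 1.69043
durvalumab+chemotherapy                    102,752.60 1.86466
durvalumab+tremelimumab+chemotherapy        99,621.76 1.68108
['chemotherapy', 'adebrelimab+chemotherapy', 'serplulimab+chemotherapy']
```

Reading: under the synthetic price/effect assumptions, adebrelimab+chemo
joins the efficiency frontier at a sequential ICER of 58,178.84 USD/QALY
and serplulimab+chemo follows at 102,307.45 USD/QALY — both above the
38,042.49 USD/QALY willingness-to-pay ceiling (3× China's per-capita GDP),
so neither would be deemed cost-effective versus chemotherapy alone.

The same machinery applied to the *published* strategy table
(`escea.synthetic.table1_fixture()`) removes the dominated and
extended-dominated strategies and leaves serplulimab+chemotherapy as the
single ICI strategy on the frontier at ≈ 80,425 USD/QALY versus
chemotherapy.

From a shell:

```bash
escea run --out results/ --seed 42 \
    --analyses basecase,frontier,dsa,psa,thresholds
```

writes `basecase.csv`, `frontier_stepwise.csv`, `tornado.csv`,
`thresholds.csv`, `psa_draws.csv`, `ceac.csv`, a JSON summary and a
SHA-256 manifest; runs are bit-reproducible per seed.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline frontier quantity from scratch: it runs the full
stepwise dominance algorithm on the published six-strategy (cost, QALY)
table and reports the sequential ICER of the sole surviving
immunochemotherapy strategy versus chemotherapy, after first exercising
the whole synthetic pipeline (reconstruction → fitting → cohort model →
economics → frontier) as a smoke check.

See `docs/methods.md` for model assumptions, parameter conventions,
numerical choices and known limitations.
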