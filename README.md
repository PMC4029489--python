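# mdscea

A lifetime Markov cohort cost-effectiveness model of **azacitidine
versus conventional care regimens** (best supportive care, low-dose and
standard-dose chemotherapy) in **high-risk myelodysplastic syndromes
(MDS)**, from the Spanish National Health System perspective in 2012
euros.

It is written for health-economics and HTA analysts who want a tested,
scriptable implementation of the full pipeline: simulating trial-like
censored time-to-event data, fitting and extrapolating parametric
survival curves, running the three-state cohort model, computing
incremental cost-effectiveness, and propagating parameter uncertainty.

## The model

Three mutually exclusive health states — MDS (start state, on first-line
treatment), AML and death — advance over 5-week (35-day) cycles. Exits
from MDS are driven by the fitted overall-survival and time-to-AML
curves as competing risks: for endpoint X, the conditional per-cycle
probability is

    q_X = 1 − S_X(t₁) / S_X(t₀),         [t₀, t₁) = [35k, 35(k+1))

with total exit 1 − (1−q_death)(1−q_aml) split in proportion to the
cumulative-hazard increments. AML carries a constant mortality of 0.135
per cycle. Two-year trial curves are fitted by right-censored maximum
likelihood (exponential, Weibull, log-normal, log-logistic; minimum-AIC
selection) and extrapolated by their closed forms. The on-treatment
fraction of the MDS state follows the Weibull treatment-cessation curve
and weights per-cycle costs; utilities are 0.67 for MDS (0.66 in the
standard-dose arm) and 0.52 for AML. Costs and effects are discounted at
3%/year; lifetime totals feed

    ICER = ΔC / ΔE,    NMB = λ·ΔQALY − ΔC    (λ = €50,000/QALY)

pairwise and against the patient-count-weighted pooled comparator
(110/79/38/20). Probabilistic sensitivity analysis resamples survival
coefficients (multivariate normal with the fit covariance), utilities
and AML mortality (beta, ±30%), and cost multipliers (normal, ±30%),
and reports cost-effectiveness acceptability curves. See
`docs/methods.md` for assumptions and conventions.

## Worked example

```python
from mdscea import load_config
from mdscea.pipeline import run_pipeline

result = run_pipeline(load_config(None), seed=3, n_psa=0)
for label, c in result.comparisons.items():
    print(f"vs {label}: ΔC €{c.delta_cost:,.0f}  ΔQALY {c.delta_qaly:.2f}  "
          f"ICER €{c.icer_per_qaly:,.0f}/QALY")
```

prints (synthetic default scenario, seed 3):

```
vs BSC: ΔC €41,363  ΔQALY 0.61  ICER €67,668/QALY
vs LDC: ΔC €30,347  ΔQALY 0.53  ICER €57,800/QALY
vs SDC: ΔC €10,753  ΔQALY 0.61  ICER €17,541/QALY
vs CCR: ΔC €33,839  ΔQALY 0.59  ICER €57,588/QALY
```

Each line is azacitidine against one comparator: the extra discounted
lifetime cost, the quality-adjusted life-years gained, and their ratio.
An ICER under the €50,000/QALY threshold (as against SDC here) means
the health gain is worth its cost at that willingness to pay; these
numbers describe the packaged *synthetic* scenario, not the original
trial, whose patient-level data is unavailable. The `examples/`
directory has one short script per capability (data simulation, survival
fitting/extrapolation, lifetime CEA, probabilistic SA), and the
`mdscea` command exposes the same stages as subcommands
(`simulate-data`, `fit-survival`, `run-cea`, `compare`, `run-psa`,
`report`).

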