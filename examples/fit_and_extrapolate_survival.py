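"""Fit parametric families to censored survival data and extrapolate.

Two years of follow-up are fitted by maximum likelihood under each
candidate family; the minimum-AIC model is selected and its closed form
extrapolates the curve to a lifetime horizon.
"""

from mdscea import default_scenario, generate_ipd, select_family, survival_at
from mdscea.survival import fit_all_families

ipd = generate_ipd(default_scenario(seed=11))

models = fit_all_families(ipd, arm="AZA", endpoint="OS")
for m in models:
    print(f"{m.family:<12} log-lik {m.log_likelihood:9.2f}  AIC {m.aic:8.2f}")

best = select_family(models)
print(f"\nselected: {best.family}  parameters: "
      + ", ".join(f"{k}={v:.3f}" for k, v in best.params.items()))

for years in (1, 2, 5, 10):
    s = survival_at(best, years * 365.25)
    print(f"S({years:>2} y) = {s:.3f}")

print(
    "\nThe AIC table compares the candidate families on the censored "
    "2-year data; the selected model's survival function S(t) is then "
    "evaluated beyond follow-up — the extrapolation that drives lifetime "
    "life-year estimates."
)
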