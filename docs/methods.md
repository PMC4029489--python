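# Methods

## The decision problem

`mdscea` implements a lifetime cost-utility model of azacitidine versus
the three conventional care regimens (CCR) used for higher-risk
myelodysplastic syndromes (MDS): best supportive care (BSC), low-dose
chemotherapy (LDC, cytarabine 150 mg/m² × 7 days) and standard-dose
chemotherapy (SDC, cytarabine 1000 mg/m² × 7 days plus an
anthracycline). The perspective is the Spanish National Health System,
costs are 2012 euros, and both costs and effects are discounted at 3%
per year. Results are lifetime discounted costs, life-years (LY) and
quality-adjusted life-years (QALY), pairwise and pooled incremental
cost-effectiveness ratios (ICERs), and probabilistic acceptability
curves against a €50,000/QALY end-of-life willingness-to-pay threshold.

## Markov cohort model

Three mutually exclusive states: **MDS** (everyone starts here, on
first-line treatment), **AML** after progression, and **death**
(absorbing). The cycle length is 35 days (five weeks, matching the
azacitidine dosing schedule); occupancy is propagated as cohort
fractions, not individuals.

Exits from MDS each cycle come from the fitted overall-survival (OS) and
time-to-AML curves. For endpoint X with survival S_X, the raw
conditional per-cycle probability over [t₀, t₁) is
q_X = 1 − S_X(t₁)/S_X(t₀). Death and progression are combined as
independent competing risks — total exit 1 − (1−q_death)(1−q_aml) —
and the total is split in proportion to the cause-specific
cumulative-hazard increments log S_X(t₀) − log S_X(t₁). The
independence assumption and the hazard-increment split are modelling
conventions; no joint distribution of death and progression is
identifiable from the published arm-level curves. Once in AML, patients
die at a constant, arm-independent probability of 0.135 per cycle and
receive BSC-pattern costs and the AML utility.

Being on versus off first-line treatment is a *cost weighting* of the
MDS state rather than a separate transition structure: the on-treatment
fraction at cycle k is the treatment-cessation curve S_cess(k·35). For
the SDC arm a single induction session is assumed, so the on-treatment
fraction is 1 in cycle 0 and 0 afterwards. There is no utility
difference on versus off treatment — a documented limitation shared
with the reference analysis.

Timing conventions: costs and utilities accrue on cycle-start occupancy
and are discounted with the factor (1+r)^(−t) evaluated at cycle start;
transitions apply at cycle end. A standard half-cycle correction
(averaging start and end occupancy) is available but **off** by
default: the reference analysis' per-cycle and lifetime figures show no
evidence of one. The run stops when the alive fraction falls below
10⁻⁶ or at 520 cycles (~50 years), which operationalizes an
"end-of-life" horizon; reaching the cap with more than ε alive flags
the trace as truncated and emits a warning.

## Survival fitting, selection and extrapolation

Candidate families are exponential, Weibull, log-normal and
log-logistic. The clinical literature this model tracks lists
"logistic" among its candidates; it is read here as *log-logistic*, the
standard survival family (a plain logistic distribution admits negative
times). Fits are maximum likelihood under right censoring, delegated to
`lifelines`' univariate fitters; each fitted model keeps its
log-likelihood, event/censoring counts, and the coefficient vector plus
covariance on the estimation scale (location and log-scale for the
log-normal, log-parameters otherwise), obtained from the natural-scale
observed-information covariance by the delta method. Family selection
minimises AIC (BIC is available by configuration); ties break toward
the most parsimonious family. Extrapolation beyond the two observed
years is the fitted closed form evaluated at any t — no hazard capping
is applied in the survival layer; the lifetime horizon cap lives in the
Markov engine. Each arm is fitted separately; no shape parameters are
shared across arms.

## Costs

Per-cycle state costs follow the published Spanish tables, shipped
under `mdscea/data/` and re-assembled component by component
(pre-medication, administration, pharmacology, follow-up, transfusions,
concurrent medication, routine tests, and for off-treatment MDS an
annualized adverse-event line charged per cycle — the printed state
totals require it as a per-cycle component).

Pharmacology supports the dose × body-surface-area × days formula. BSA
is not printed anywhere; 1.70 m² is adopted, back-calculated from the
low-dose cytarabine row (48.38 / (0.0271·150·7) ≈ 1.700). The published
rows imply slightly different BSAs (1.687–1.700 m²), so the printed
per-cycle pharmacology figures are carried verbatim as the canonical
values and the formula is provided for constructing new regimens.
Although the reference analysis states that drug wastage was assumed,
its printed costs match exact-milligram pricing; the default
`wastage_mode` is therefore `none`, with whole-vial round-up available
when vial sizes are configured. Two further published discrepancies are
taken at face value rather than "corrected": the SDC administration
cost (€16,344.02, not the €20,801.48 implied by 28 inpatient days at
€742.91) and the SDC on-treatment total's possible double-counting of
hospital days with routine tests. The text's BSC per-cycle cost of
€1,772 corresponds to the off-treatment column (the on-treatment column
prints €1,426.21); both are representable.

Adverse-event costing converts annualized per-patient episode rates to
per-cycle cost: rate · (35/365.25) · episode cost.

## Incremental analysis and the pooled comparator

ICERs are ΔC/ΔE with the ratio left undefined (not ±∞) at zero effect
difference; net monetary benefit is WTP·ΔQALY − ΔC and "cost-effective"
means NMB > 0. The pooled CCR comparator uses the trial's treatment
pattern (azacitidine 110, BSC 79, LDC 38, SDC 20 patients) in one of
two modes: `weight_outcomes` (default) averages the per-arm cost/LY/QALY
totals on both sides and recomputes one ICER — the only mode that
yields a coherent pooled arm for the PSA — while `weight_icers`
averages the pairwise ICERs directly, the convention the reference
analysis describes. Neither mode reproduces that analysis' printed
pooled row exactly; its exact pooling is unrecoverable from the
publication, so the printed values are carried as a validation fixture
and the discrepancy is left visible rather than guessed away. ICERs are
kept unrounded internally and rounded to whole euros only for display.

## Probabilistic sensitivity analysis

One joint parameter draw per iteration; the deterministic cohort model
is re-run per arm per draw (second-order Monte Carlo — "50,000
simulated individuals" is read as 50,000 parameter draws of the cohort
model, consistent with a *parametric* simulation; the package default
is 50,000 with smaller sizes used in tests and examples):

- survival, time-to-AML and cessation coefficients: multivariate normal
  on the estimation scale with the fitted covariance (a symmetric PSD
  square root via eigendecomposition tolerates near-singular fits);
- utilities and the AML per-cycle mortality: beta, moment-matched to
  the central value with a 95% interval of ±30% of the mean, truncated
  to [0, 1]; infeasible variances are truncated to the feasible bound
  and logged;
- state cost totals: normal multipliers, mean 1, 95% interval ±30%,
  truncated at zero (dosing/resource-use uncertainty).

"±30% intervals" for parameters without empirical uncertainty is
operationalized as a 95% interval of ±30% of the central value
(mean ± 1.96·sd). Which parameters carry the ±30% assumption is
user-editable in the sampling spec rather than hard-coded. The AML
utility and AML mortality are drawn once per iteration (shared across
arms); curves, costs and the MDS utility are drawn per arm,
independently — arm-to-arm correlation of these inputs is not
identifiable from the publication. Beta draws map a shared standard
normal deviate through the beta quantile function so results vary
continuously with the global `dispersion_scale`; at scale 0 every draw
reproduces the deterministic point estimate exactly. Draws whose model
run fails or returns non-finite increments are excluded and counted;
more than 5% failures aborts the run as a mis-specified spec. CEACs are
the fraction of retained draws with positive NMB on a strictly
increasing WTP grid.

## Synthetic trial data

No patient-level data from the registration trial is deposited, so the
pipeline is exercised on pseudo individual-patient data with the
structure the analysis assumes: per-arm log-normal OS and time-to-AML,
Weibull cessation, continuous times in days, and administrative
censoring at 730 days. Arm sizes default to the trial's 110/79/38/20
pattern. The trial's absolute per-arm medians were never published —
only azacitidine's OS gains (about 12.9/9.1/8.7 months over
BSC/LDC/SDC) — so the default location parameters anchor an azacitidine
median OS of 24.5 months (745 days) and set BSC/LDC/SDC at 353/468/480
days to reproduce those gains. `sigma_log` defaults to 1.1 for OS
(lifetime log-normal extrapolation of a high-risk MDS cohort requires a
heavy right tail to give plausible lifetime survivorship) and 1.0 for
time-to-AML; cessation uses Weibull shape 1.3 with median on-treatment
times of roughly 315/180/112/100 days. Endpoints are drawn
independently within a patient: the real OS/AML correlation is *not*
emulated, visit-schedule rounding is absent, and no covariates
(IPSS risk, cytogenetics) or response outcomes exist. Consequently,
passing tests demonstrate the correctness of the machinery under its
own distributional assumptions — recovery of generating parameters,
internal consistency, oracle agreement — not fidelity to the real
trial's numbers. The published lifetime totals and PSA probabilities
depend on unpublished fitted survival parameters and are documented as
non-reproducible; validation against the publication is restricted to
quantities computable from printed inputs (per-cycle cost tables,
per-arm lifetime totals, increments, ICERs, weighted pools).

## Numerical choices and test/oracle sizes

- Occupancy conservation is maintained to 10⁻¹² per cycle; death is
  monotone by construction.
- Survival ratios are clipped to [0, 1]; survival values are floored at
  10⁻³⁰⁰ inside logs; a cohort whose OS curve has reached zero at the
  cycle start is absorbed (transition (1, 0) with a flag).
- When cumulative-hazard increments vanish at floating-point
  resolution, the competing-risk split falls back to raw conditional
  probabilities as weights.
- Determinism: all randomness flows through `numpy.random.Generator`;
  the pipeline derives independent stage seeds from one master seed via
  `SeedSequence`, and seeded reruns are byte-identical on all numeric
  artifacts (the run manifest alone carries wall-clock timestamps).
- Oracle problem sizes, chosen to make Monte-Carlo error small relative
  to the tolerances: 20,000 subjects for parameter recovery (2% bias
  bound), 100 replicates of n = 5,000 for the family-selection study,
  a 10⁶-subject latent-time simulation for the competing-risk split,
  100,000 individually simulated patients for the cohort-vs-
  microsimulation check (3 Monte-Carlo SE), and 10,000 draws for the
  CEAC seed-stability check. The acceptance script's synthetic PSA uses
  2,000 draws by default (`--n-psa` raises it).

## Known limitations

- Cause-specific independence of death and progression, and the
  proportional-hazard-increment split, are untestable conventions here.
- No background (age-specific other-cause) mortality; the OS curve is
  the only source of pre-AML death, exactly as in the reference model.
- No tunnel states and no utility decrement attached to adverse events
  or treatment status within MDS.
- The individual-level simulator exists only as a test oracle; the
  cohort engine is the analysis tool.
- The pooled-CCR row of the reference publication is reproducible by
  neither implemented weighting mode; see the incremental-analysis
  section above.
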