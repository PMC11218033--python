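# cogeffort

Simulation and analysis pipeline for a **calibrated cognitive-effort
choice study**: how willingness to deploy cognitive effort for reward
relates to visual short-term memory capacity, depressive traits, chronic
stress and reward anticipation.

The paradigm translates the rodent cognitive effort task to a human
change-detection setting.  Participants rate their excitement for rewards
(8 incentive-delay trials), complete a 120-trial change-detection
calibration phase (set sizes 2/4/6/8), and then make 30 binary choices
between a **low-effort/low-reward** trial (smaller array, 1 point) and a
**high-effort/high-reward** trial (larger array, 10 points).  Task
difficulty is calibrated per participant: with the whole-display capacity
estimate at set size 4,

```
k = N * (h - f) / (1 - f)
```

(`N` set size, `h` hit rate, `f` false-alarm rate), participants with
`k <= 3` choose between set sizes (2, 6) and those with `k > 3` between
(4, 8).  Participants choosing the high-effort option on strictly more
than 70% of trials form the *high-effort* phenotype.

Effort choices and their latencies are modelled with a four-parameter
Wiener drift-diffusion model — drift rate `v`, boundary separation `a`,
relative starting point `w` (upper boundary = high-effort choice) and
non-decision time `t0`, unit diffusion coefficient — via exact
first-passage-time series densities, simulation, per-participant maximum
likelihood and a hierarchical Bayesian fit, together with a full
parameter-recovery harness.

No external data are needed: the `cohort` module generates synthetic
cohorts with the statistical structure the analysis assumes (correlated
traits, capacity-limited change detection, diffusion-generated choices
with capacity coupled to the starting point), so every downstream stage is
testable end to end.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1 --out results
python analysis/02_capacity_and_exclusions.py --out results
python analysis/03_statistical_battery.py --out results
python analysis/04_fit_ddm.py --seed 1 --out results          # add --method hierarchical for MCMC
python analysis/05_parameter_recovery.py --seed 1 --out results
python analysis/06_report.py --out results
```

On a 120-participant cohort (`--n-participants 120`) this prints, among
other output:

```
kept 107 of 120 participants
K at set size 4: mean 3.40, SD 0.79
high-effort group: 63.6%
logistic regression (effort group): K estimate beta 0.792 (e^b 2.21, p 0.009);
  trait p-values bdi_prop 0.65, pss 0.31, anticipation 0.97
accuracy ANOVA, trial-type effect: F(1,99) = 201.1, ges = 0.522
high- vs low-effort group (Welch t, Bonferroni family of 4):
  v: t(72.8) = 3.51, p = 0.00311, d = 0.81
  w: t(72.8) = 2.86, p = 0.0223, d = 0.66
```

Reading: only the capacity estimate predicts effort-group membership (the
trait predictors sit at their null rates, as the generator intends);
accuracy is far higher on the easier low-effort trials; and the
high-effort group shows a higher drift rate and a starting point shifted
toward the high-effort boundary — the same qualitative pattern the
statistical battery is designed to detect.  The recovery script shows
truth–estimate correlations near 1.0 at 500 trials per participant
degrading visibly at the study's own 30-trial scale, which the report
flags as a low-information regime.

The same stages can be run as one configured unit:

```python
from cogeffort import RunConfig, run_pipeline
run_pipeline(RunConfig(seed=1), "results/run1")   # writes manifest + report.md
```

## Layout

- `src/cogeffort/` — the library: `config`, `cohort` (synthetic data),
  `capacity` (Cowan's K), `ddm` (Wiener model), `hddm` (hierarchical
  MCMC), `stats` (the battery), `validation` (simulation studies),
  `pipeline` (orchestration and reporting).
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and whole-pipeline validity tests.
- `docs/methods.md` — models, assumptions, parameter defaults and
  numerical choices.
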