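# ste-trials

Design, interim monitoring and simulation of **single-arm two-stage phase II
trials** whose primary endpoint is a nested discrete-time binary survival
endpoint (e.g. progression-free survival assessed every 3 months and
dichotomized at 12 months).

The package provides:

- **`trial_core`** — domain types (assessment schedules, designs, patient
  records) and the interim-snapshot aggregation: per-transition
  evaluable/survivor counts `(n_k, x_k)` and pending groups `m_{k'}` of
  patients last confirmed alive at assessment `k'`.
- **`classic_designs`** — exact binomial operating characteristics for the
  two reference stage-1 rules (threshold on long-term survivors, threshold
  on short-term survivors) and an exhaustive optimal/minimax design search
  using the nested-binomial type I error and power with a binding stop.
- **`ste_cp`** — conditional-power futility rule: discrete Kaplan–Meier
  transition MLEs with a constant-hazard plug-in for unobserved
  transitions, conditional power by Monte Carlo *and* by an exact binomial
  convolution.
- **`ste_pos`** — posterior-predictive futility rule: negative-log-Gamma
  transition priors whose product is Beta(α, 1), factorized grid
  posteriors (no MCMC needed), and the posterior predictive probability of
  success with draws shared across pending groups.
- **`sim_engine`** — data generation (Weibull event times solved from
  discrete survival targets, Poisson accrual), full two-stage trial
  simulation for all four decision rules with common-random-number
  pairing, operating-characteristics estimation and futility-cutoff
  calibration to a type I error target.
- **`cli_io`** — a `ste-trials` command-line tool and CSV/YAML/JSON I/O.

## Command line

```bash
ste-trials example                       # bundled 18-patient worked example
ste-trials design-search spec.yaml       # optimal two-stage design
ste-trials interim cp patients.csv design.yaml
ste-trials interim pos patients.csv design.yaml
ste-trials calibrate scenario.yaml --method ste_cp
ste-trials simulate scenario.yaml --n-replicates 10000
```

Patient tables are CSV with columns `id, recruit_time, event_time`
(empty = no event) and optional `lost_to_followup` (0/1; counted as
failure at the final analysis).  Design/scenario files are YAML; see
`tests/test_cli_io.py` for complete examples.  Exit codes: 0 success,
2 validation error, 3 no feasible design.

## Python API sketch

```python
from ste_trials import (
    build_interim_snapshot, conditional_mles, conditional_power_exact,
    probability_of_success, TransitionPrior, ScenarioSpec, calibrate_cutoff,
)
from ste_trials.datasets import example_patients, example_design, EXAMPLE_SCHEDULE

snap = build_interim_snapshot(example_patients(), EXAMPLE_SCHEDULE, 28.0, n_total=38)
est = conditional_mles(snap, plug_in_rate=0.317)
cp = conditional_power_exact(snap, est, r_final=6)            # 0.8170
pos = probability_of_success(snap, TransitionPrior.unit_rate(4), 6,
                             n_draws=100_000, seed=1)         # ~0.775
```

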