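"""Trial simulation: Weibull event times, Poisson accrual, two-stage
conduct under each continuation rule, operating characteristics and
futility-cutoff calibration.

Event times are drawn from a Weibull survival function solved to hit the
scenario's short- and long-term survival rates exactly; accrual is a
homogeneous Poisson process (exponential inter-arrival gaps), with an
optional variant that releases Poisson-distributed monthly cohorts at
whole-month ticks.  The interim takes place as soon as the last stage-1
patient has an observed first assessment (for the long-term stage-1 rule:
an observed final assessment); on continuation the remaining patients are
recruited from the interim onwards and the final analysis applies the
strict ``survivors > r`` test to all patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .ste_cp import conditional_mles, conditional_power_exact
from .ste_pos import TransitionPrior, probability_of_success
from .trial_core import (
    AssessmentSchedule,
    InterimSnapshot,
    KunzRule,
    SimonRule,
    SteCpRule,
    StePosRule,
    TrialDesign,
)

__all__ = [
    "ScenarioSpec",
    "TrialOutcome",
    "OperatingCharacteristics",
    "CalibrationResult",
    "solve_weibull",
    "weibull_survival",
    "simulate_trial",
    "estimate_oc",
    "calibrate_cutoff",
]

ACCRUAL_MODELS = ("poisson_process", "monthly_counts")


def solve_weibull(
    p1: float, p4: float, t1: float = 3.0, t4: float = 12.0
) -> tuple[float, float]:
    """Weibull (shape, scale) with ``S(t1) = p1`` and ``S(t4) = p4``.

    ``S(t) = exp(-(t / scale) ** shape)`` gives the closed form
    ``shape = log(log p4 / log p1) / log(t4 / t1)`` and the scale from
    either constraint.  ``p4 == p1`` leaves the shape undefined and is
    rejected; a scenario with constant hazard corresponds to
    ``p4 == p1 ** (t4 / t1)`` (shape 1), not to equal rates.
    """
    if not 0.0 < p4 <= p1 < 1.0:
        raise ValueError(f"need 0 < p4 <= p1 < 1, got p1={p1}, p4={p4}")
    if not t1 < t4:
        raise ValueError(f"need t1 < t4, got {t1}, {t4}")
    if p4 == p1:
        raise ValueError(
            "p4 == p1 leaves the Weibull shape undefined; pick p4 < p1 "
            "(an exponential tail corresponds to p4 = p1 ** (t4/t1))"
        )
    shape = math.log(math.log(p4) / math.log(p1)) / math.log(t4 / t1)
    scale = t1 / (-math.log(p1)) ** (1.0 / shape)
    return shape, scale


def weibull_survival(t: float, shape: float, scale: float) -> float:
    """``S(t) = exp(-(t / scale) ** shape)``."""
    return math.exp(-((t / scale) ** shape))


@dataclass(frozen=True)
class ScenarioSpec:
    """One data-generating configuration for the simulation engine.

    ``p1_true`` / ``p4_true`` are the true survival rates at the first and
    the final assessment; the Weibull parameters are solved from them, not
    user-set.  ``accrual_rate`` is the mean number of patients per month.
    """

    p1_true: float
    p4_true: float
    accrual_rate: float
    design: TrialDesign
    schedule: AssessmentSchedule = field(default_factory=lambda: AssessmentSchedule(4, 3.0))
    accrual_model: str = "poisson_process"
    pos_draws: int = 2_000
    pos_grid_size: int = 1_024

    def __post_init__(self) -> None:
        if not self.accrual_rate > 0:
            raise ValueError(f"accrual_rate must be > 0, got {self.accrual_rate}")
        if self.accrual_model not in ACCRUAL_MODELS:
            raise ValueError(f"accrual_model must be one of {ACCRUAL_MODELS}")
        # validates the rate pair and fails fast on an unsolvable scenario
        solve_weibull(
            self.p1_true,
            self.p4_true,
            self.schedule.time_of(1),
            self.schedule.time_of(self.schedule.k_star),
        )

    @property
    def weibull_shape(self) -> float:
        return self._weibull()[0]

    @property
    def weibull_scale(self) -> float:
        return self._weibull()[1]

    def _weibull(self) -> tuple[float, float]:
        return solve_weibull(
            self.p1_true,
            self.p4_true,
            self.schedule.time_of(1),
            self.schedule.time_of(self.schedule.k_star),
        )


@dataclass(frozen=True)
class TrialOutcome:
    """Result of one simulated trial."""

    stopped_early: bool
    rejected: bool
    n_used: int
    duration_months: float
    statistic: float


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte Carlo operating characteristics with standard errors."""

    method_label: str
    pet: float
    reject_rate: float
    expected_n: float
    mean_duration: float
    pet_se: float
    reject_rate_se: float
    expected_n_se: float
    mean_duration_se: float
    n_replicates: int


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated futility cutoff and the achieved type I error rate."""

    cutoff: float
    type1_at_cutoff: float
    method_label: str
    n_replicates: int
    grid_step: float


@dataclass(frozen=True)
class _TrialData:
    """Raw draws for one replicate, reusable across decision rules.

    Stage-2 arrivals are stored as inter-arrival gaps so that the same
    draws can be replayed from whatever interim time a rule implies.
    """

    arrivals1: np.ndarray
    events1: np.ndarray
    gaps2: np.ndarray
    events2: np.ndarray


def _draw_arrivals(rng: np.random.Generator, rate: float, count: int, model: str) -> np.ndarray:
    if model == "poisson_process":
        return np.cumsum(rng.exponential(1.0 / rate, size=count))
    times: list[float] = []
    month = 0
    while len(times) < count:
        times.extend([float(month)] * int(rng.poisson(rate)))
        month += 1
    return np.asarray(times[:count])


def _draw_trial_data(scenario: ScenarioSpec, rng: np.random.Generator) -> _TrialData:
    design = scenario.design
    shape, scale = scenario._weibull()
    n1, n2 = design.n_stage1, design.n_stage2
    arrivals1 = _draw_arrivals(rng, scenario.accrual_rate, n1, scenario.accrual_model)
    events1 = scale * rng.weibull(shape, size=n1)
    if scenario.accrual_model == "poisson_process":
        gaps2 = rng.exponential(1.0 / scenario.accrual_rate, size=n2)
    else:
        raw = _draw_arrivals(rng, scenario.accrual_rate, n2, scenario.accrual_model)
        gaps2 = np.diff(np.concatenate([[0.0], raw]))
    events2 = scale * rng.weibull(shape, size=n2)
    return _TrialData(arrivals1, events1, gaps2, events2)


def _snapshot_from_arrays(
    recruit: np.ndarray,
    event: np.ndarray,
    schedule: AssessmentSchedule,
    interim_time: float,
    n_total: int,
) -> InterimSnapshot:
    """Array-based snapshot builder (hot path of the simulator).

    Mirrors :func:`ste_trials.trial_core.build_interim_snapshot` for fully
    observed event times; equivalence of the two routes is asserted in the
    test suite.
    """
    ks, dt = schedule.k_star, schedule.spacing
    n_eval = [0] * ks
    x_surv = [0] * ks
    pending = [0] * ks
    known = 0
    failures = 0
    pending[0] += n_total - len(recruit)
    for a, e in zip(recruit, event):
        k_prime = 0
        died = False
        for k in range(1, ks + 1):
            if a + dt * k > interim_time:
                break
            n_eval[k - 1] += 1
            if e > dt * k:
                x_surv[k - 1] += 1
                k_prime = k
            else:
                died = True
                break
        if died:
            failures += 1
        elif k_prime == ks:
            known += 1
        else:
            pending[k_prime] += 1
    return InterimSnapshot(
        schedule=schedule,
        interim_time=interim_time,
        n_total=n_total,
        n_evaluable=tuple(n_eval),
        x_survivors=tuple(x_surv),
        pending=tuple(pending),
        known_survivors=known,
        failures=failures,
    )


def _interim_statistic(
    scenario: ScenarioSpec,
    design: TrialDesign,
    data: _TrialData,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Returns (statistic, threshold, interim_time) for the design's rule."""
    schedule = scenario.schedule
    rule = design.continuation_rule
    horizon = schedule.time_of(schedule.k_star)
    if isinstance(rule, SimonRule):
        interim = float(data.arrivals1[-1]) + horizon
        stat = float(np.sum(data.events1 > horizon))
        return stat, float(rule.r1), interim
    interim = float(data.arrivals1[-1]) + schedule.time_of(1)
    if isinstance(rule, KunzRule):
        stat = float(np.sum(data.events1 > schedule.time_of(1)))
        return stat, float(rule.s1), interim
    snapshot = _snapshot_from_arrays(
        data.arrivals1, data.events1, schedule, interim, design.n_total
    )
    if isinstance(rule, SteCpRule):
        estimate = conditional_mles(snapshot, design.p_lte_alt, mode=rule.plug_in)
        stat = conditional_power_exact(snapshot, estimate, design.r_final)
        return stat, rule.cutoff, interim
    if isinstance(rule, StePosRule):
        prior = TransitionPrior(shape=1.0 / schedule.k_star, rate=rule.prior_rate)
        stat = probability_of_success(
            snapshot,
            prior,
            design.r_final,
            n_draws=scenario.pos_draws,
            seed=rng,
            grid_size=scenario.pos_grid_size,
        )
        return stat, rule.cutoff, interim
    raise TypeError(f"unsupported continuation rule {rule!r}")


def _final_rejects(scenario: ScenarioSpec, design: TrialDesign, data: _TrialData) -> bool:
    horizon = scenario.schedule.time_of(scenario.schedule.k_star)
    survivors = int(np.sum(data.events1 > horizon)) + int(np.sum(data.events2 > horizon))
    return survivors > design.r_final


def simulate_trial(
    scenario: ScenarioSpec,
    seed: Optional[Union[int, np.random.Generator]] = None,
    design: Optional[TrialDesign] = None,
    data: Optional[_TrialData] = None,
) -> TrialOutcome:
    """Simulate one trial under the scenario's (or the given) design."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    design = design or scenario.design
    if data is None:
        data = _draw_trial_data(scenario, rng)
    stat, threshold, interim = _interim_statistic(scenario, design, data, rng)
    if not stat > threshold:
        return TrialOutcome(
            stopped_early=True,
            rejected=False,
            n_used=design.n_stage1,
            duration_months=interim,
            statistic=stat,
        )
    horizon = scenario.schedule.time_of(scenario.schedule.k_star)
    arrivals2 = interim + np.cumsum(data.gaps2)
    duration = float(arrivals2[-1]) + horizon if arrivals2.size else interim
    return TrialOutcome(
        stopped_early=False,
        rejected=_final_rejects(scenario, design, data),
        n_used=design.n_total,
        duration_months=duration,
        statistic=stat,
    )


def _summarize(label: str, outcomes: list[TrialOutcome]) -> OperatingCharacteristics:
    n = len(outcomes)
    stopped = np.array([o.stopped_early for o in outcomes], dtype=float)
    rejected = np.array([o.rejected for o in outcomes], dtype=float)
    n_used = np.array([o.n_used for o in outcomes], dtype=float)
    duration = np.array([o.duration_months for o in outcomes], dtype=float)

    def prop_se(p: float) -> float:
        return math.sqrt(p * (1.0 - p) / n)

    return OperatingCharacteristics(
        method_label=label,
        pet=float(stopped.mean()),
        reject_rate=float(rejected.mean()),
        expected_n=float(n_used.mean()),
        mean_duration=float(duration.mean()),
        pet_se=prop_se(float(stopped.mean())),
        reject_rate_se=prop_se(float(rejected.mean())),
        expected_n_se=float(n_used.std(ddof=1) / math.sqrt(n)),
        mean_duration_se=float(duration.std(ddof=1) / math.sqrt(n)),
        n_replicates=n,
    )


def _rule_label(design: TrialDesign) -> str:
    return {
        SimonRule: "simon",
        KunzRule: "kunz",
        SteCpRule: "ste_cp",
        StePosRule: "ste_pos",
    }[type(design.continuation_rule)]


def estimate_oc(
    scenario: ScenarioSpec,
    n_replicates: int,
    seed: Optional[int] = None,
    designs: Optional[Sequence[TrialDesign]] = None,
) -> Union[OperatingCharacteristics, dict[str, OperatingCharacteristics]]:
    """Monte Carlo operating characteristics.

    With ``designs`` given, every design is evaluated on the *same*
    simulated datasets (common random numbers), so differences between
    methods stem from their continuation rules alone; a dict keyed by rule
    label is returned.  Otherwise the scenario's own design is used and a
    single summary is returned.
    """
    if n_replicates < 100:
        raise ValueError(f"n_replicates must be >= 100, got {n_replicates}")
    rng = np.random.default_rng(seed)
    paired = designs is not None
    design_list = list(designs) if paired else [scenario.design]
    outcomes: dict[str, list[TrialOutcome]] = {
        _rule_label(d): [] for d in design_list
    }
    for _ in range(n_replicates):
        data = _draw_trial_data(scenario, rng)
        for d in design_list:
            outcomes[_rule_label(d)].append(
                simulate_trial(scenario, seed=rng, design=d, data=data)
            )
    summaries = {label: _summarize(label, outs) for label, outs in outcomes.items()}
    if paired:
        return summaries
    return next(iter(summaries.values()))


def calibrate_cutoff(
    null_scenario: ScenarioSpec,
    method: str,
    alpha_target: float,
    n_replicates: int = 20_000,
    seed: Optional[int] = None,
    grid_step: float = 0.001,
) -> CalibrationResult:
    """Choose the futility cutoff so the null type I error rate is met.

    Simulates replicate trials under the null scenario; for each, records
    the interim statistic and whether the trial *would* reject at the end
    had it continued.  The returned cutoff is the smallest value ``c`` on
    the grid with ``P(statistic > c and final rejection) <= alpha_target``
    — the type I error rate lands just below the target.
    """
    if not 0.0 < alpha_target < 1.0:
        raise ValueError(f"alpha_target must be in (0, 1), got {alpha_target}")
    if method not in ("ste_cp", "ste_pos"):
        raise ValueError(f"method must be 'ste_cp' or 'ste_pos', got {method!r}")
    base = null_scenario.design
    if method == "ste_cp":
        probe = replace(base, continuation_rule=SteCpRule(cutoff=0.0))
    else:
        rule = base.continuation_rule
        prior_rate = rule.prior_rate if isinstance(rule, StePosRule) else 1.0
        probe = replace(base, continuation_rule=StePosRule(cutoff=0.0, prior_rate=prior_rate))

    rng = np.random.default_rng(seed)
    stats_arr = np.empty(n_replicates)
    rejects = np.empty(n_replicates, dtype=bool)
    for i in range(n_replicates):
        data = _draw_trial_data(null_scenario, rng)
        stat, _, _ = _interim_statistic(null_scenario, probe, data, rng)
        stats_arr[i] = stat
        rejects[i] = _final_rejects(null_scenario, probe, data)

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    # type I error as a function of the cutoff, via a single sort of the
    # rejecting replicates' statistics
    reject_stats = np.sort(stats_arr[rejects])
    exceed = reject_stats.size - np.searchsorted(reject_stats, grid, side="right")
    type1 = exceed / n_replicates
    feasible = np.nonzero(type1 <= alpha_target)[0]
    idx = int(feasible[0])
    return CalibrationResult(
        cutoff=float(grid[idx]),
        type1_at_cutoff=float(type1[idx]),
        method_label=method,
        n_replicates=n_replicates,
        grid_step=grid_step,
    )
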