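"""Bundled worked example: one interim dataset of a two-stage trial.

Eighteen stage-1 patients of a 38-patient trial (first assessment at
month 3, final at month 12), observed at an interim 28 months after the
first recruitment.  The recruit and event times are fixed so the example
is fully reproducible; it exercises every part of an interim analysis:
observed deaths, completed follow-ups and administratively censored
(pending) patients.
"""

from __future__ import annotations

from .classic_designs import DesignSearchSpec
from .trial_core import (
    AssessmentSchedule,
    KunzRule,
    PatientRecord,
    TrialDesign,
)

__all__ = [
    "EXAMPLE_INTERIM_TIME",
    "EXAMPLE_SCHEDULE",
    "example_patients",
    "example_design",
    "example_search_spec",
]

# (recruit_time, event_time) in months; event times beyond month 12 mean
# long-term survival
_EXAMPLE_TIMES: tuple[tuple[float, float], ...] = (
    (0.0, 4.61),
    (0.0, 0.66),
    (1.0, 3.70),
    (6.0, 13.51),
    (7.0, 6.86),
    (7.0, 12.94),
    (8.0, 18.71),
    (11.0, 8.64),
    (11.0, 0.90),
    (11.0, 2.91),
    (20.0, 5.11),
    (20.0, 0.81),
    (21.0, 4.85),
    (22.0, 2.20),
    (22.0, 15.21),
    (22.0, 4.77),
    (24.0, 0.81),
    (25.0, 13.04),
)

EXAMPLE_INTERIM_TIME = 28.0
EXAMPLE_SCHEDULE = AssessmentSchedule(k_star=4, spacing=3.0)


def example_patients() -> list[PatientRecord]:
    """The 18 stage-1 patient records of the worked example."""
    return [PatientRecord(recruit_time=a, event_time=e) for a, e in _EXAMPLE_TIMES]


def example_design(continuation_rule=None) -> TrialDesign:
    """The first-scenario reference design: n_I=18, n=38, s1=13, r=6.

    Hypothesized long-term rates 0.127 vs 0.317 and short-term rates
    0.7 vs 0.9, alpha 0.10, power 0.95.  Pass ``continuation_rule`` to
    swap the stage-1 rule while keeping the shared design parameters.
    """
    return TrialDesign(
        n_stage1=18,
        n_total=38,
        r_final=6,
        continuation_rule=continuation_rule or KunzRule(s1=13),
        p_lte_null=0.127,
        p_lte_alt=0.317,
        p_ste_null=0.7,
        p_ste_alt=0.9,
        alpha=0.10,
        power_target=0.95,
    )


def example_search_spec(scenario: int = 1) -> DesignSearchSpec:
    """Design-search inputs of the three benchmark scenarios."""
    rates = {1: (0.127, 0.317), 2: (0.25, 0.5), 3: (0.55, 0.8)}
    if scenario not in rates:
        raise ValueError(f"scenario must be 1, 2 or 3, got {scenario}")
    p0, p1 = rates[scenario]
    return DesignSearchSpec(
        p_lte_null=p0,
        p_lte_alt=p1,
        p_ste_null=0.7,
        p_ste_alt=0.9,
        alpha=0.10,
        beta=0.05,
        n_max=60,
        criterion="optimal",
    )
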