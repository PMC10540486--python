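"""Domain types for two-stage trials with nested discrete-time survival endpoints.

A trial follows each patient over a grid of post-baseline assessments
(every ``spacing`` months, ``k_star`` of them).  Survival is nested: a
patient can only be evaluated at assessment ``k`` if they were alive at
assessment ``k - 1``.  At an interim analysis the recruited patients are
aggregated into per-transition evaluable/survivor counts ``(n_k, x_k)``
and "pending" groups ``m_{k'}`` of patients last confirmed alive at
assessment ``k'`` whose later assessments have not happened yet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import pandas as pd

__all__ = [
    "AssessmentSchedule",
    "SimonRule",
    "KunzRule",
    "SteCpRule",
    "StePosRule",
    "TrialDesign",
    "PatientRecord",
    "InterimSnapshot",
    "DecisionResult",
    "build_interim_snapshot",
    "final_analysis",
    "snapshot_to_frame",
]


@dataclass(frozen=True)
class AssessmentSchedule:
    """Discrete post-baseline measurement grid.

    Parameters
    ----------
    k_star:
        Number of post-baseline assessments; the last one (``k = k_star``)
        defines the long-term endpoint.
    spacing:
        Calendar time between consecutive assessments, in months.
    """

    k_star: int
    spacing: float = 3.0

    def __post_init__(self) -> None:
        if self.k_star < 1:
            raise ValueError(f"k_star must be >= 1, got {self.k_star}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")

    @property
    def assessment_times(self) -> list[float]:
        """Calendar offsets of assessments 1..k_star since recruitment."""
        return [self.spacing * k for k in range(1, self.k_star + 1)]

    def time_of(self, k: int) -> float:
        """Offset of assessment ``k`` (months since recruitment)."""
        if not 0 <= k <= self.k_star:
            raise ValueError(f"assessment index {k} outside 0..{self.k_star}")
        return self.spacing * k


@dataclass(frozen=True)
class SimonRule:
    """Stage-1 rule on long-term survivors: continue iff more than ``r1``."""

    r1: int


@dataclass(frozen=True)
class KunzRule:
    """Stage-1 rule on short-term survivors: continue iff more than ``s1``."""

    s1: int


@dataclass(frozen=True)
class SteCpRule:
    """Continue iff the interim conditional power exceeds ``cutoff``.

    ``plug_in`` selects how unobserved transitions are imputed, see
    :func:`ste_trials.ste_cp.conditional_mles`.
    """

    cutoff: float
    plug_in: str = "constant_hazard"

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError(f"cutoff must be in [0, 1], got {self.cutoff}")


@dataclass(frozen=True)
class StePosRule:
    """Continue iff the posterior predictive probability of success
    exceeds ``cutoff``.

    ``prior_rate`` is the rate parameter of the per-transition
    negative-log-Gamma prior (shape is always ``1 / k_star``); the product
    of the transition probabilities is then a priori Beta(prior_rate, 1).
    """

    cutoff: float
    prior_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError(f"cutoff must be in [0, 1], got {self.cutoff}")
        if not self.prior_rate > 0:
            raise ValueError(f"prior_rate must be > 0, got {self.prior_rate}")


ContinuationRule = Union[SimonRule, KunzRule, SteCpRule, StePosRule]


@dataclass(frozen=True)
class TrialDesign:
    """Two-stage design: sample sizes, final threshold and continuation rule.

    The final analysis rejects the null hypothesis iff the number of
    long-term survivors among all ``n_total`` patients is strictly greater
    than ``r_final``.
    """

    n_stage1: int
    n_total: int
    r_final: int
    continuation_rule: ContinuationRule
    p_lte_null: float
    p_lte_alt: float
    p_ste_null: Optional[float] = None
    p_ste_alt: Optional[float] = None
    alpha: float = 0.10
    power_target: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.n_stage1 < self.n_total:
            raise ValueError(
                f"need 0 < n_stage1 < n_total, got {self.n_stage1}, {self.n_total}"
            )
        if not 0 <= self.r_final < self.n_total:
            raise ValueError(f"r_final must be in [0, n_total), got {self.r_final}")
        if not 0 < self.p_lte_null < self.p_lte_alt < 1:
            raise ValueError(
                "need 0 < p_lte_null < p_lte_alt < 1, got "
                f"{self.p_lte_null}, {self.p_lte_alt}"
            )
        for ste, lte, name in (
            (self.p_ste_null, self.p_lte_null, "null"),
            (self.p_ste_alt, self.p_lte_alt, "alt"),
        ):
            if ste is not None and ste < lte:
                raise ValueError(
                    f"nesting violated: p_ste_{name}={ste} < p_lte_{name}={lte}"
                )

    @property
    def n_stage2(self) -> int:
        return self.n_total - self.n_stage1


@dataclass(frozen=True)
class PatientRecord:
    """Follow-up of one patient.

    ``event_time`` is continuous months since recruitment; ``None`` means
    no event was observed within the follow-up horizon.  A death is only
    *observed* at scheduled assessments: the decision rules never use the
    continuous value directly.
    """

    recruit_time: float
    event_time: Optional[float] = None
    lost_to_followup: bool = False

    def __post_init__(self) -> None:
        if self.recruit_time < 0:
            raise ValueError(f"recruit_time must be >= 0, got {self.recruit_time}")
        if self.event_time is not None and not self.event_time > 0:
            raise ValueError(f"event_time must be > 0, got {self.event_time}")

    def alive_at(self, t: float) -> bool:
        """Survival status at time ``t`` months after recruitment."""
        return self.event_time is None or self.event_time > t


@dataclass(frozen=True)
class InterimSnapshot:
    """Aggregated interim view of a trial.

    Attributes
    ----------
    n_evaluable, x_survivors:
        Per-transition counts for assessments ``1..k_star``: patients with
        an available measurement at ``k`` who were alive at ``k - 1``, and
        how many of them survived.
    pending:
        Sizes ``m_{k'}`` for ``k' = 0..k_star - 1`` of groups last
        confirmed alive at assessment ``k'`` with later assessments still
        pending.  ``m_0`` includes the not-yet-recruited stage-2 patients.
    known_survivors:
        Patients already confirmed alive at the final assessment.
    failures:
        Patients whose observed death (or loss to follow-up) rules out
        long-term survival.
    """

    schedule: AssessmentSchedule
    interim_time: float
    n_total: int
    n_evaluable: tuple[int, ...]
    x_survivors: tuple[int, ...]
    pending: tuple[int, ...]
    known_survivors: int
    failures: int

    def __post_init__(self) -> None:
        ks = self.schedule.k_star
        if len(self.n_evaluable) != ks or len(self.x_survivors) != ks:
            raise ValueError("transition counts must have length k_star")
        if len(self.pending) != ks:
            raise ValueError("pending must have length k_star (k' = 0..k_star-1)")
        for k, (n, x) in enumerate(zip(self.n_evaluable, self.x_survivors), start=1):
            if x > n:
                raise ValueError(f"x_{k}={x} > n_{k}={n}")
            if k >= 2 and n > self.x_survivors[k - 2]:
                raise ValueError(
                    f"n_{k}={n} exceeds prior survivors x_{k-1}={self.x_survivors[k-2]}"
                )
        total = self.known_survivors + sum(self.pending) + self.failures
        if total != self.n_total:
            raise ValueError(
                f"conservation violated: known {self.known_survivors} + pending "
                f"{sum(self.pending)} + failures {self.failures} != n_total {self.n_total}"
            )

    @property
    def transition_counts(self) -> list[tuple[int, int]]:
        """List of ``(n_k, x_k)`` pairs for ``k = 1..k_star``."""
        return list(zip(self.n_evaluable, self.x_survivors))


@dataclass(frozen=True)
class DecisionResult:
    """Outcome of an interim decision rule."""

    statistic: float
    cutoff: float
    continue_flag: bool
    method_label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.statistic <= 1.0:
            raise ValueError(f"statistic must be in [0, 1], got {self.statistic}")
        if self.continue_flag != (self.statistic > self.cutoff):
            raise ValueError("continue_flag inconsistent with statistic > cutoff")


def build_interim_snapshot(
    patients: Sequence[PatientRecord],
    schedule: AssessmentSchedule,
    interim_time: float,
    n_total: int,
) -> InterimSnapshot:
    """Aggregate patient follow-up into an interim snapshot.

    Assessment ``k`` of a patient is *available* iff
    ``recruit_time + spacing * k <= interim_time`` (boundary inclusive) and
    the patient survived all earlier assessments.  A patient's ``k'`` is
    the last available assessment at which they were alive; patients with
    an observed death contribute to the transition counts up to and
    including the death assessment and never enter a pending group.
    Unrecruited stage-2 patients are counted in ``m_0``.
    """
    if interim_time < 0:
        raise ValueError(f"interim_time must be >= 0, got {interim_time}")
    if len(patients) > n_total:
        raise ValueError(f"{len(patients)} patients exceed n_total={n_total}")
    for p in patients:
        if p.recruit_time > interim_time:
            raise ValueError(
                f"patient recruited at {p.recruit_time} after interim {interim_time}"
            )

    ks, dt = schedule.k_star, schedule.spacing
    n_eval = [0] * ks
    x_surv = [0] * ks
    pending = [0] * ks
    known = 0
    failures = 0
    any_data = False

    pending[0] += n_total - len(patients)

    for p in patients:
        k_prime = 0
        died = False
        for k in range(1, ks + 1):
            if p.recruit_time + dt * k > interim_time:
                break
            any_data = True
            n_eval[k - 1] += 1
            if p.alive_at(dt * k):
                x_surv[k - 1] += 1
                k_prime = k
            else:
                died = True
                break
        if died or p.lost_to_followup:
            failures += 1
        elif k_prime == ks:
            known += 1
        else:
            pending[k_prime] += 1

    if patients and not any_data:
        raise ValueError(
            "no assessable data: interim_time precedes every patient's first assessment"
        )

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


def final_analysis(
    patients: Sequence[PatientRecord],
    schedule: AssessmentSchedule,
    design: TrialDesign,
) -> bool:
    """Final test decision: reject iff long-term survivors > ``r_final``.

    Every patient must have complete follow-up: reached the final
    assessment, died, or be flagged lost to follow-up (the latter counts
    as failure — the conservative censoring rule).
    """
    if len(patients) != design.n_total:
        raise ValueError(
            f"final analysis needs all {design.n_total} patients, got {len(patients)}"
        )
    horizon = schedule.time_of(schedule.k_star)
    survivors = 0
    for p in patients:
        if p.lost_to_followup:
            continue
        if p.alive_at(horizon):
            survivors += 1
    return survivors > design.r_final


def snapshot_to_frame(snapshot: InterimSnapshot) -> pd.DataFrame:
    """Tabular export of a snapshot: transition counts and pending groups."""
    ks = snapshot.schedule.k_star
    rows = []
    for k in range(1, ks + 1):
        rows.append(
            {
                "k": k,
                "n_k": snapshot.n_evaluable[k - 1],
                "x_k": snapshot.x_survivors[k - 1],
                "m_kprime": snapshot.pending[k - 1] if k - 1 < ks else None,
            }
        )
    frame = pd.DataFrame(rows)
    # m_{k'} is indexed k' = 0..k_star-1; align it alongside k = 1..k_star
    frame.insert(3, "kprime", range(ks))
    return frame
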