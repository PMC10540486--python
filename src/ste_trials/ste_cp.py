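"""Conditional-power interim rule for nested discrete-time survival data.

The per-transition survival probabilities are estimated by their maximum
likelihood values ``x_k / n_k`` (the discrete Kaplan–Meier factors);
transitions with no evaluable patient receive a plug-in value.  Pending
patients are projected to the final assessment with the telescoped
conditional-to-end probabilities, and the conditional power is the
probability that the projected number of long-term survivors exceeds the
final success threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import stats

from .trial_core import DecisionResult, InterimSnapshot, SteCpRule, TrialDesign

__all__ = [
    "ConditionalSurvivalEstimate",
    "conditional_mles",
    "conditional_power",
    "conditional_power_exact",
    "decide_cp",
]

PLUG_IN_MODES = ("constant_hazard", "literal")


@dataclass(frozen=True)
class ConditionalSurvivalEstimate:
    """Per-transition conditional survival estimates ``p_{k|k-1}``.

    ``observed[k-1]`` is False where the value was plugged in rather than
    estimated from data.
    """

    step_probs: tuple[float, ...]
    observed: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.step_probs) != len(self.observed):
            raise ValueError("step_probs and observed must have equal length")
        for p in self.step_probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"step probability {p} outside [0, 1]")

    @property
    def k_star(self) -> int:
        return len(self.step_probs)

    def tail_prob(self, k_prime: int) -> float:
        """Conditional-to-end probability ``p_{k*|k'}`` (telescoped product)."""
        if not 0 <= k_prime <= self.k_star:
            raise ValueError(f"k_prime {k_prime} outside 0..{self.k_star}")
        return math.prod(self.step_probs[k_prime:])

    def tail_probs(self) -> tuple[float, ...]:
        """``p_{k*|k'}`` for every ``k' = 0..k_star`` (last entry is 1)."""
        return tuple(self.tail_prob(kp) for kp in range(self.k_star + 1))


def conditional_mles(
    snapshot: InterimSnapshot,
    plug_in_rate: Optional[float] = None,
    mode: str = "constant_hazard",
) -> ConditionalSurvivalEstimate:
    """Maximum likelihood transition estimates with plug-in for empty cells.

    ``p_hat_{k|k-1} = x_k / n_k`` wherever ``n_k > 0``.  Transitions with
    no evaluable patient are imputed from ``plug_in_rate`` (the
    hypothesized long-term rate, typically the alternative value):

    - ``mode="constant_hazard"`` (default): every imputed transition gets
      the constant per-step value ``plug_in_rate ** (1 / k_star)``, so a
      fully unobserved chain telescopes to ``plug_in_rate`` at the end —
      the constant-conditional-probability assumption applied per step.
    - ``mode="literal"``: transition ``k`` gets
      ``plug_in_rate ** (1 / (k_star - k + 1))``, the conditional-to-end
      root taken from the last confirmed assessment ``k - 1``.  Kept for
      sensitivity analysis; it does not telescope consistently.
    """
    if mode not in PLUG_IN_MODES:
        raise ValueError(f"mode must be one of {PLUG_IN_MODES}, got {mode!r}")
    ks = snapshot.schedule.k_star
    steps: list[float] = []
    observed: list[bool] = []
    for k in range(1, ks + 1):
        n_k = snapshot.n_evaluable[k - 1]
        x_k = snapshot.x_survivors[k - 1]
        if n_k > 0:
            steps.append(x_k / n_k)
            observed.append(True)
            continue
        if plug_in_rate is None:
            raise ValueError(
                f"transition {k} has no evaluable patients and no plug_in_rate given"
            )
        if not 0.0 < plug_in_rate < 1.0:
            raise ValueError(f"plug_in_rate must be in (0, 1), got {plug_in_rate}")
        if mode == "constant_hazard":
            steps.append(plug_in_rate ** (1.0 / ks))
        else:
            steps.append(plug_in_rate ** (1.0 / (ks - k + 1)))
        observed.append(False)
    return ConditionalSurvivalEstimate(tuple(steps), tuple(observed))


def _pending_groups(
    snapshot: InterimSnapshot, estimate: ConditionalSurvivalEstimate
) -> list[tuple[int, float]]:
    """Nonempty pending groups as ``(m_{k'}, p_{k*|k'})`` pairs."""
    if estimate.k_star != snapshot.schedule.k_star:
        raise ValueError("estimate and snapshot disagree on k_star")
    return [
        (m, estimate.tail_prob(kp))
        for kp, m in enumerate(snapshot.pending)
        if m > 0
    ]


def conditional_power(
    snapshot: InterimSnapshot,
    estimate: ConditionalSurvivalEstimate,
    r_final: int,
    n_mc: int = 10_000,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> float:
    """Monte Carlo conditional power.

    Per iteration, ``y_{k'} ~ Binomial(m_{k'}, p_hat_{k*|k'})`` is drawn
    independently for every pending group (including the not-yet-recruited
    stage-2 patients in ``m_0``); success means
    ``known_survivors + sum y_{k'} > r_final`` (strict).
    """
    if n_mc < 1:
        raise ValueError(f"n_mc must be >= 1, got {n_mc}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    total = np.zeros(n_mc, dtype=np.int64)
    for m, p in _pending_groups(snapshot, estimate):
        total += rng.binomial(m, p, size=n_mc)
    return float(np.mean(total + snapshot.known_survivors > r_final))


def conditional_power_exact(
    snapshot: InterimSnapshot,
    estimate: ConditionalSurvivalEstimate,
    r_final: int,
) -> float:
    """Exact conditional power by convolving the pending-group binomials."""
    need = r_final - snapshot.known_survivors + 1
    if need <= 0:
        return 1.0
    pmf = np.ones(1)
    for m, p in _pending_groups(snapshot, estimate):
        pmf = np.convolve(pmf, stats.binom.pmf(np.arange(m + 1), m, p))
    if need >= pmf.size:
        return 0.0
    return float(pmf[need:].sum())


def decide_cp(
    snapshot: InterimSnapshot,
    design: TrialDesign,
    plug_in_rate: Optional[float] = None,
    n_mc: int = 10_000,
    seed: Optional[int] = None,
    exact: bool = True,
) -> DecisionResult:
    """Interim continue/stop decision by conditional power.

    The trial continues iff CP strictly exceeds the rule's cutoff.  By
    default the exact convolution value is used; set ``exact=False`` for
    the Monte Carlo estimate.
    """
    rule = design.continuation_rule
    if not isinstance(rule, SteCpRule):
        raise TypeError("design must carry a SteCpRule continuation rule")
    if plug_in_rate is None:
        plug_in_rate = design.p_lte_alt
    estimate = conditional_mles(snapshot, plug_in_rate, mode=rule.plug_in)
    if exact:
        cp = conditional_power_exact(snapshot, estimate, design.r_final)
    else:
        cp = conditional_power(snapshot, estimate, design.r_final, n_mc, seed)
    return DecisionResult(
        statistic=cp,
        cutoff=rule.cutoff,
        continue_flag=cp > rule.cutoff,
        method_label="ste_cp",
    )
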