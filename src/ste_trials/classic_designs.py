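"""Exact binomial operating characteristics and design search for the
reference two-stage designs.

Two stage-1 rules are covered: the classical rule on long-term survivors
(continue iff more than ``r1`` of the stage-1 patients survive long term)
and the short-term-endpoint rule (continue iff more than ``s1`` of the
stage-1 patients survive the first assessment).  For the latter, the
joint distribution of short- and long-term survivors is nested binomial:

    S ~ Binomial(n_I, p_ste),    X1 | S ~ Binomial(S, p_lte / p_ste),
    X2 ~ Binomial(n - n_I, p_lte),

the trial continues iff ``S > s1`` and rejects iff ``X1 + X2 > r``.

The design search calibrates the type I error rate with a *binding*
stopping rule evaluated at the hypothesized null short-term rate (the
same nested-binomial formula at the null rates); power uses the binding
rule at the alternative rates.  The classical non-binding type I error
rate — the plain upper binomial tail, which ignores stopping — is exposed
separately as :func:`kunz_type1`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import stats

from .trial_core import KunzRule, SimonRule, TrialDesign

__all__ = [
    "DesignSearchSpec",
    "pet_simon",
    "pet_kunz",
    "kunz_type1",
    "kunz_reject_prob",
    "kunz_power",
    "expected_sample_size",
    "search_kunz_design",
    "simon_design_oc",
]


@dataclass(frozen=True)
class DesignSearchSpec:
    """Inputs of the exhaustive two-stage design search."""

    p_lte_null: float
    p_lte_alt: float
    p_ste_null: float
    p_ste_alt: float
    alpha: float = 0.10
    beta: float = 0.05
    n_max: int = 60
    criterion: Literal["optimal", "minimax"] = "optimal"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ValueError("alpha and beta must lie in (0, 1)")
        if self.n_max < 2:
            raise ValueError(f"n_max must be >= 2, got {self.n_max}")
        if not 0 < self.p_lte_null < self.p_lte_alt < 1:
            raise ValueError("need 0 < p_lte_null < p_lte_alt < 1")
        if self.p_ste_null < self.p_lte_null or self.p_ste_alt < self.p_lte_alt:
            raise ValueError("short-term rates must dominate long-term rates")
        if self.criterion not in ("optimal", "minimax"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


def _check_threshold(thresh: int, n1: int, name: str) -> None:
    if not 0 <= thresh <= n1:
        raise ValueError(f"{name} must be in [0, {n1}], got {thresh}")


def pet_simon(r1: int, p: float, n1: int) -> float:
    """Probability of early termination of the long-term stage-1 rule:
    ``P(X <= r1)`` with ``X ~ Binomial(n1, p)``."""
    _check_threshold(r1, n1, "r1")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    return float(stats.binom.cdf(r1, n1, p))


def pet_kunz(s1: int, p_ste: float, n1: int) -> float:
    """Probability of early termination of the short-term stage-1 rule:
    ``P(S <= s1)`` with ``S ~ Binomial(n1, p_ste)``."""
    _check_threshold(s1, n1, "s1")
    if not 0.0 <= p_ste <= 1.0:
        raise ValueError(f"p_ste must be in [0, 1], got {p_ste}")
    return float(stats.binom.cdf(s1, n1, p_ste))


def kunz_type1(n: int, r: int, p0: float) -> float:
    """Non-binding type I error rate: ``P(X > r)``, ``X ~ Binomial(n, p0)``.

    This is the rejection probability when futility stopping is ignored
    entirely (the trial never stops), the strictest possible bound.
    """
    if not 0 <= r < n:
        raise ValueError(f"r must be in [0, n), got r={r}, n={n}")
    return float(stats.binom.sf(r, n, p0))


def kunz_reject_prob(
    n1: int, n: int, s1: int, r: int, p_ste: float, p_lte: float
) -> float:
    """Exact rejection probability of the binding short-term rule.

    ``P(S > s1 and X1 + X2 > r)`` under the nested-binomial model at the
    given short-/long-term rates.  Evaluated at the null rates this is the
    binding type I error rate; at the alternative rates it is the power.
    """
    _check_threshold(s1, n1, "s1")
    if not 0 <= r < n:
        raise ValueError(f"r must be in [0, n), got r={r}, n={n}")
    if p_lte > p_ste:
        raise ValueError(f"nesting violated: p_lte={p_lte} > p_ste={p_ste}")
    return float(_joint_tail_matrix(n1, n, p_ste, p_lte)[s1, r])


def kunz_power(design: TrialDesign, p_ste: float, p_lte: float) -> float:
    """Power of a short-term-rule design at the given true rates
    (binding stopping rule)."""
    rule = design.continuation_rule
    if not isinstance(rule, KunzRule):
        raise TypeError("design must carry a KunzRule continuation rule")
    return kunz_reject_prob(
        design.n_stage1, design.n_total, rule.s1, design.r_final, p_ste, p_lte
    )


def expected_sample_size(design: TrialDesign, p_ste: float) -> float:
    """``n_I + (1 - PET) * (n - n_I)`` with PET from the stage-1 rule."""
    rule = design.continuation_rule
    if not isinstance(rule, KunzRule):
        raise TypeError("design must carry a KunzRule continuation rule")
    pet = pet_kunz(rule.s1, p_ste, design.n_stage1)
    return design.n_stage1 + (1.0 - pet) * design.n_stage2


class NoFeasibleDesignError(RuntimeError):
    """No design within ``n_max`` satisfies the error constraints."""


def search_kunz_design(spec: DesignSearchSpec) -> TrialDesign:
    """Exhaustive search for the optimal or minimax short-term-rule design.

    Enumerates ``(n_I, n <= n_max, s1 <= n_I, r < n)``; keeps designs whose
    binding type I error rate at the null rates is at most ``alpha`` and
    whose binding power at the alternative rates is at least ``1 - beta``.
    Returns the design minimizing the expected sample size under the null
    ("optimal") or the total sample size ("minimax"); ties are broken by
    smaller ``n``, then smaller ``n_I``, then larger ``s1``.

    For fixed ``(n_I, n, s1)`` the smallest feasible ``r`` maximizes power
    and leaves the expected sample size unchanged, and the expected sample
    size is decreasing in ``s1``, so per ``(n_I, n)`` only the largest
    ``s1`` with a feasible ``(r, power)`` pair needs to be kept.
    """
    best_key: Optional[tuple] = None
    best: Optional[TrialDesign] = None

    for n in range(2, spec.n_max + 1):
        for n1 in range(1, n):
            pet0 = stats.binom.cdf(np.arange(n1 + 1), n1, spec.p_ste_null)
            # joint tail P(S > s1, X > r) for every (s1, r) via suffix sums
            null_by_s1_r = _joint_tail_matrix(
                n1, n, spec.p_ste_null, spec.p_lte_null
            )
            alt_by_s1_r = _joint_tail_matrix(n1, n, spec.p_ste_alt, spec.p_lte_alt)
            for s1 in range(n1, -1, -1):
                null_tail = null_by_s1_r[s1]  # decreasing in r
                feasible_r = np.nonzero(null_tail <= spec.alpha)[0]
                if feasible_r.size == 0:
                    continue
                r = int(feasible_r[0])
                if r >= n:
                    continue
                power = float(alt_by_s1_r[s1, r])
                if power < 1.0 - spec.beta:
                    continue
                expected_n = n1 + (1.0 - pet0[s1]) * (n - n1)
                objective = expected_n if spec.criterion == "optimal" else n
                key = (objective, n, n1, -s1)
                if best_key is None or key < best_key:
                    best_key = key
                    best = TrialDesign(
                        n_stage1=n1,
                        n_total=n,
                        r_final=r,
                        continuation_rule=KunzRule(s1=s1),
                        p_lte_null=spec.p_lte_null,
                        p_lte_alt=spec.p_lte_alt,
                        p_ste_null=spec.p_ste_null,
                        p_ste_alt=spec.p_ste_alt,
                        alpha=spec.alpha,
                        power_target=1.0 - spec.beta,
                    )
                break  # largest feasible s1 minimizes E[N] for this (n1, n)

    if best is None:
        raise NoFeasibleDesignError(
            f"no design with n <= {spec.n_max} meets alpha={spec.alpha}, "
            f"power={1 - spec.beta}"
        )
    return best


def _joint_tail_matrix(n1: int, n: int, p_ste: float, p_lte: float) -> np.ndarray:
    """``out[s1, r] = P(S > s1 and X1 + X2 > r)`` for all thresholds.

    Vectorized over the stage-1 survivor count: ``T[s]`` is the pmf of
    ``X1 + X2`` given ``S = s``, obtained by convolving the conditional
    stage-1 pmf with the stage-2 pmf.
    """
    q = p_lte / p_ste if p_ste > 0 else 0.0
    n2 = n - n1
    s_grid = np.arange(n1 + 1)
    p_s = stats.binom.pmf(s_grid, n1, p_ste)
    pmf2 = stats.binom.pmf(np.arange(n2 + 1), n2, p_lte)
    # lower-triangular matrix of Binomial(s, q) pmfs
    jj = np.arange(n1 + 1)
    pmf1 = stats.binom.pmf(jj[None, :], s_grid[:, None], q)
    pmf1 = np.where(jj[None, :] <= s_grid[:, None], pmf1, 0.0)
    # T[s, t] = sum_j pmf1[s, j] * pmf2[t - j]
    conv = np.zeros((n1 + 1, n + 1))
    for j in range(n1 + 1):
        conv[:, j : j + n2 + 1] += pmf1[:, j : j + 1] * pmf2[None, :]
    weighted = p_s[:, None] * conv
    # suffix over s (S > s1), then suffix over t (X > r)
    suffix_s = np.vstack([np.cumsum(weighted[::-1], axis=0)[::-1], np.zeros(n + 1)])[
        1:
    ]
    tail = np.flip(np.cumsum(np.flip(suffix_s, axis=1), axis=1), axis=1)
    tail = np.hstack([tail[:, 1:], np.zeros((n1 + 1, 1))])
    return tail


def simon_design_oc(design: TrialDesign, p: float) -> tuple[float, float]:
    """Exact rejection probability and PET of a long-term-rule design.

    With a binding stage-1 rule at a single true rate ``p``:
    continue iff ``X_1 > r1`` (stage-1 long-term survivors), reject iff
    ``X_1 + X_2 > r``.  Returns ``(rejection probability, PET)``.
    """
    rule = design.continuation_rule
    if not isinstance(rule, SimonRule):
        raise TypeError("design must carry a SimonRule continuation rule")
    n1, n, r1, r = design.n_stage1, design.n_total, rule.r1, design.r_final
    _check_threshold(r1, n1, "r1")
    if not 0 <= r < n:
        raise ValueError(f"r must be in [0, n), got {r}")
    n2 = n - n1
    x1 = np.arange(r1 + 1, n1 + 1)
    pmf1 = stats.binom.pmf(x1, n1, p)
    # P(X2 > r - x1), padded so that r - x1 < 0 maps to probability 1
    sf2 = np.concatenate([[1.0], stats.binom.sf(np.arange(n2 + 1), n2, p)])
    idx = np.clip(r - x1 + 1, 0, n2 + 1)
    reject = float(pmf1 @ sf2[idx]) if x1.size else 0.0
    return reject, pet_simon(r1, p, n1)
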