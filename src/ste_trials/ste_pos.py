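"""Posterior-predictive interim rule for nested discrete-time survival data.

Each conditional survival probability ``p_{k|k-1}`` receives a
negative-log-Gamma prior: ``-log p ~ Gamma(shape, rate)`` with
``shape = 1 / k_star``.  The sum of ``k_star`` such Gamma variables is
``Gamma(1, rate)``, i.e. exponential, so the product of the transition
probabilities — the long-term survival probability of a newly enrolled
patient — is a priori ``Beta(rate, 1)``.  Combined with the factorized
binomial likelihood the transition posteriors stay mutually independent
and one-dimensional, so they are represented on deterministic grids and
sampled by inverse-CDF lookup; no MCMC is required.

Numerically the posterior of ``u = -log p`` is handled on the transformed
axis ``v = u ** shape``, which absorbs the ``u ** (shape - 1)`` prior
singularity exactly: the density in ``v`` is proportional to
``exp(-(rate + x) * u) * (1 - exp(-u)) ** (n - x)`` with ``u = v ** (1/shape)``,
a smooth bounded function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .trial_core import DecisionResult, InterimSnapshot, StePosRule, TrialDesign

__all__ = [
    "TransitionPrior",
    "TransitionPosterior",
    "alpha_from_prior_mean",
    "transition_posterior",
    "sample_prior_product",
    "probability_of_success",
    "decide_pos",
]

DEFAULT_GRID_SIZE = 4096
_LOG_DENSITY_DROP = 45.0  # density support cut: exp(-45) ~ 3e-20


def alpha_from_prior_mean(mean: float) -> float:
    """Beta(alpha, 1) parameter with the requested prior mean.

    The Beta(alpha, 1) mean is ``alpha / (alpha + 1)``, hence
    ``alpha = mean / (1 - mean)``.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must be in (0, 1), got {mean}")
    return mean / (1.0 - mean)


@dataclass(frozen=True)
class TransitionPrior:
    """Negative-log-Gamma prior of one conditional survival probability.

    ``-log p ~ Gamma(shape, rate)`` with density on (0, 1)
    ``f(p) ∝ (-log p) ** (shape - 1) * p ** (rate - 1)``.
    """

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if not self.shape > 0:
            raise ValueError(f"shape must be > 0, got {self.shape}")
        if not self.rate > 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")

    @classmethod
    def for_long_term_mean(cls, k_star: int, mean: float) -> "TransitionPrior":
        """Prior whose k_star-fold product is Beta(alpha, 1) with the
        given mean: ``shape = 1/k_star``, ``rate = mean / (1 - mean)``."""
        return cls(shape=1.0 / k_star, rate=alpha_from_prior_mean(mean))

    @classmethod
    def unit_rate(cls, k_star: int) -> "TransitionPrior":
        """Rate-1 prior (``shape = 1/k_star``); the induced long-term
        prior is uniform, Beta(1, 1)."""
        return cls(shape=1.0 / k_star, rate=1.0)


class TransitionPosterior:
    """Grid representation of one transition-probability posterior.

    Built from a :class:`TransitionPrior` and binomial counts
    ``(n_k, x_k)``; with zero counts the posterior equals the prior.
    """

    def __init__(
        self,
        shape: float,
        rate: float,
        n_k: int,
        x_k: int,
        grid_size: int = DEFAULT_GRID_SIZE,
    ) -> None:
        if not 0 <= x_k <= n_k:
            raise ValueError(f"need 0 <= x_k <= n_k, got x_k={x_k}, n_k={n_k}")
        if grid_size < 16:
            raise ValueError(f"grid_size too small: {grid_size}")
        self.shape = float(shape)
        self.rate = float(rate)
        self.n_k = int(n_k)
        self.x_k = int(x_k)
        self._point: Optional[float] = None

        u_lo, u_hi = self._support()
        v = np.linspace(u_lo**self.shape, u_hi**self.shape, grid_size)
        u = v ** (1.0 / self.shape)
        logd = -(self.rate + self.x_k) * u
        fails = self.n_k - self.x_k
        if fails > 0:
            with np.errstate(divide="ignore"):
                logd += fails * np.log1p(-np.exp(-u))
        dens = np.exp(logd - logd.max())
        mass = np.trapezoid(dens, v)
        self._v = v
        self._u = u
        self._pdf_v = dens / mass
        cdf = np.concatenate(
            [[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(v))]
        )
        self._cdf = cdf / cdf[-1]

    def _support(self) -> tuple[float, float]:
        """Interval of u = -log p outside which the density is negligible."""
        rx = self.rate + self.x_k
        fails = self.n_k - self.x_k
        if fails == 0:
            return 0.0, _LOG_DENSITY_DROP / rx

        def logd(u: float) -> float:
            return -rx * u + fails * math.log1p(-math.exp(-u))

        u_mode = math.log((self.rate + self.n_k) / rx)
        target = logd(u_mode) - _LOG_DENSITY_DROP
        lo, hi = u_mode * 1e-12, u_mode
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if logd(mid) < target:
                lo = mid
            else:
                hi = mid
        u_lo = lo
        lo, hi = u_mode, u_mode + 1.0
        while logd(hi) > target:
            hi *= 2.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if logd(mid) < target:
                hi = mid
            else:
                lo = mid
        return u_lo, hi

    @classmethod
    def from_prior(
        cls, prior: TransitionPrior, n_k: int, x_k: int, grid_size: int = DEFAULT_GRID_SIZE
    ) -> "TransitionPosterior":
        return cls(prior.shape, prior.rate, n_k, x_k, grid_size)

    @classmethod
    def point_mass(cls, value: float) -> "TransitionPosterior":
        """Degenerate posterior concentrated at ``value`` (testing aid:
        with point-mass posteriors the PoS reduces to conditional power)."""
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"value must be in [0, 1], got {value}")
        obj = cls.__new__(cls)
        obj.shape = float("nan")
        obj.rate = float("nan")
        obj.n_k = 0
        obj.x_k = 0
        obj._point = value
        return obj

    @property
    def grid(self) -> np.ndarray:
        """Grid of probability values p (decreasing in u, increasing here)."""
        if self._point is not None:
            return np.array([self._point])
        return np.exp(-self._u)[::-1]

    def pdf(self, p: Union[float, np.ndarray]) -> np.ndarray:
        """Posterior density of the transition probability at ``p``."""
        if self._point is not None:
            raise ValueError("point-mass posterior has no density")
        p_arr = np.atleast_1d(np.asarray(p, dtype=float))
        u = -np.log(p_arr)
        v = u**self.shape
        f_v = np.interp(v, self._v, self._pdf_v, left=0.0, right=0.0)
        with np.errstate(divide="ignore"):
            jac = self.shape * u ** (self.shape - 1.0) / p_arr
        return f_v * jac

    def total_mass(self) -> float:
        """Integral of the normalized density (1 up to quadrature error)."""
        if self._point is not None:
            return 1.0
        return float(np.trapezoid(self._pdf_v, self._v))

    def moment(self, order: int = 1) -> float:
        """Posterior ``E[p ** order]``."""
        if self._point is not None:
            return self._point**order
        return float(np.trapezoid(np.exp(-order * self._u) * self._pdf_v, self._v))

    @property
    def mean(self) -> float:
        return self.moment(1)

    @property
    def variance(self) -> float:
        return self.moment(2) - self.moment(1) ** 2

    def sample(
        self, n_draws: int, rng: Optional[Union[int, np.random.Generator]] = None
    ) -> np.ndarray:
        """Inverse-CDF draws of the transition probability."""
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        if self._point is not None:
            return np.full(n_draws, self._point)
        v = np.interp(rng.uniform(size=n_draws), self._cdf, self._v)
        return np.exp(-(v ** (1.0 / self.shape)))


def transition_posterior(
    prior: TransitionPrior, n_k: int, x_k: int, grid_size: int = DEFAULT_GRID_SIZE
) -> TransitionPosterior:
    """Posterior of one conditional survival probability given counts."""
    return TransitionPosterior.from_prior(prior, n_k, x_k, grid_size)


def _as_priors(
    priors: Union[TransitionPrior, Sequence[TransitionPrior]], k_star: int
) -> list[TransitionPrior]:
    if isinstance(priors, TransitionPrior):
        return [priors] * k_star
    priors = list(priors)
    if len(priors) != k_star:
        raise ValueError(f"need one prior per transition ({k_star}), got {len(priors)}")
    return priors


def sample_prior_product(
    prior: TransitionPrior,
    k_star: int,
    n_draws: int,
    seed: Optional[Union[int, np.random.Generator]] = None,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> np.ndarray:
    """Draws of the product of ``k_star`` independent prior transition
    probabilities; distributed Beta(rate, 1) when ``shape = 1/k_star``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    post = TransitionPosterior.from_prior(prior, 0, 0, grid_size)
    draws = np.ones(n_draws)
    for _ in range(k_star):
        draws = draws * post.sample(n_draws, rng)
    return draws


def probability_of_success(
    snapshot: InterimSnapshot,
    priors: Union[TransitionPrior, Sequence[TransitionPrior]],
    r_final: int,
    n_draws: int = 10_000,
    seed: Optional[Union[int, np.random.Generator]] = None,
    grid_size: int = DEFAULT_GRID_SIZE,
    posteriors: Optional[Sequence[TransitionPosterior]] = None,
) -> float:
    """Posterior predictive probability of success.

    Per iteration one value of every transition posterior is drawn and
    *shared across all pending groups*, preserving the between-group
    correlation induced by the common parameters; pending survivors are
    then drawn binomially with the telescoped conditional-to-end
    probabilities, and success means
    ``known_survivors + sum y_{k'} > r_final``.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    ks = snapshot.schedule.k_star
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if posteriors is None:
        prior_list = _as_priors(priors, ks)
        posteriors = [
            TransitionPosterior.from_prior(
                prior_list[k - 1],
                snapshot.n_evaluable[k - 1],
                snapshot.x_survivors[k - 1],
                grid_size,
            )
            for k in range(1, ks + 1)
        ]
    elif len(posteriors) != ks:
        raise ValueError(f"need one posterior per transition ({ks})")

    steps = np.column_stack([post.sample(n_draws, rng) for post in posteriors])
    # tails[:, k'] = prod_{k > k'} steps[:, k]  (conditional-to-end draws)
    tails = np.ones((n_draws, ks + 1))
    tails[:, :ks] = np.cumprod(steps[:, ::-1], axis=1)[:, ::-1]
    total = np.zeros(n_draws, dtype=np.int64)
    for kp, m in enumerate(snapshot.pending):
        if m > 0:
            total += rng.binomial(m, tails[:, kp])
    return float(np.mean(total + snapshot.known_survivors > r_final))


def decide_pos(
    snapshot: InterimSnapshot,
    design: TrialDesign,
    n_draws: int = 10_000,
    seed: Optional[Union[int, np.random.Generator]] = None,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> DecisionResult:
    """Interim continue/stop decision by posterior predictive probability
    of success; continue iff PoS strictly exceeds the rule's cutoff."""
    rule = design.continuation_rule
    if not isinstance(rule, StePosRule):
        raise TypeError("design must carry a StePosRule continuation rule")
    prior = TransitionPrior(shape=1.0 / snapshot.schedule.k_star, rate=rule.prior_rate)
    pos = probability_of_success(
        snapshot, prior, design.r_final, n_draws=n_draws, seed=seed, grid_size=grid_size
    )
    return DecisionResult(
        statistic=pos,
        cutoff=rule.cutoff,
        continue_flag=pos > rule.cutoff,
        method_label="ste_pos",
    )
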