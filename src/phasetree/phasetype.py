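"""Coxian phase-type (PH) distributions.

A phase-type distribution is the law of the time to absorption of a
continuous-time Markov chain with ``n`` transient states ("phases") and one
absorbing state.  It is parameterised by the initial distribution ``alpha``
over the phases, the ``n x n`` sub-generator ``Q`` of rates among phases, and
the exit-rate vector ``q`` into the absorbing state, with the generator
identity ``Q @ 1 + q = 0`` holding row by row.

The Coxian subfamily restricts the chain to a forward path: from phase ``i``
the process either exits (rate ``(1 - p_i) * lam_i``) or moves on to phase
``i + 1`` (rate ``p_i * lam_i``), and it always starts in phase 1.  Despite
the restriction, Coxian distributions can approximate any positive-valued
distribution, which makes them a flexible model for waiting times to
speciation or extinction in macroevolution: a lineage drifts through latent
"ages" in which its chance of speciating rises or falls.

Two ready-made parameterisations with three free parameters ``(x, y, z)`` are
provided: :func:`ph_dec`, whose exit rates strictly decrease with phase
(speciation becomes less likely as a species ages), and :func:`ph_inc`, the
mirror image with strictly increasing exit rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from ._matexp import expm_batch

__all__ = [
    "CoxianPH",
    "build_coxian",
    "ph_dec",
    "ph_inc",
    "moments_dec",
    "moments_inc",
]

#: survival probabilities below this are treated as numerically zero when
#: forming hazards (the hazard is then reported as saturated / undefined).
SURVIVAL_FLOOR = 1e-12


def _validate_rates(lambdas: np.ndarray, ps: np.ndarray) -> None:
    if lambdas.ndim != 1 or lambdas.size < 1:
        raise ValueError("lambdas must be a non-empty 1-d sequence")
    if ps.shape != (lambdas.size - 1,):
        raise ValueError(
            f"need {lambdas.size - 1} continuation probabilities for "
            f"{lambdas.size} phases, got {ps.size}"
        )
    if np.any(lambdas <= 0):
        raise ValueError("phase exit rates must be strictly positive")
    if np.any((ps <= 0) | (ps > 1)):
        raise ValueError("continuation probabilities must lie in (0, 1]")


@dataclass(frozen=True)
class CoxianPH:
    """A Coxian phase-type distribution ``PH(alpha, Q)``.

    Attributes
    ----------
    alpha : ndarray, shape (n,)
        Initial distribution over phases; ``[1, 0, ..., 0]`` in the Coxian
        canonical form.
    Q : ndarray, shape (n, n)
        Sub-generator: strictly negative diagonal, non-negative
        superdiagonal, zero elsewhere.
    q : ndarray, shape (n,)
        Exit-rate vector; ``Q @ 1 + q = 0``.
    """

    alpha: np.ndarray
    Q: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        q = np.atleast_1d(np.asarray(self.q, dtype=float))
        n = q.size
        if Q.shape != (n, n) or alpha.shape != (n,):
            raise ValueError("inconsistent dimensions for alpha, Q, q")
        if np.any(np.diag(Q) >= 0):
            raise ValueError("diagonal of Q must be strictly negative")
        off = Q - np.diag(np.diag(Q))
        if np.any(off < 0):
            raise ValueError("off-diagonal entries of Q must be non-negative")
        if np.any(q < 0) or not np.any(q > 0):
            raise ValueError("exit rates must be >= 0 with at least one > 0")
        if not np.allclose(Q.sum(axis=1) + q, 0.0, atol=1e-10):
            raise ValueError("generator identity Q@1 + q = 0 violated")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "q", q)

    @property
    def n(self) -> int:
        """Number of non-absorbing phases."""
        return self.q.size

    # -- distribution functions -------------------------------------------

    def pdf(self, t):
        """Density ``alpha @ expm(Q t) @ q`` at time(s) ``t >= 0``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be non-negative")
        front = self._front(t)
        return front @ self.q if t.ndim == 0 else (front * self.q).sum(-1)

    def cdf(self, t):
        """``1 - alpha @ expm(Q t) @ 1`` at time(s) ``t >= 0``."""
        return 1.0 - self.sf(t)

    def sf(self, t):
        """Survival function ``alpha @ expm(Q t) @ 1``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be non-negative")
        return self._front(t).sum(-1)

    def _front(self, t: np.ndarray) -> np.ndarray:
        """``alpha @ expm(Q t)`` for scalar or vector ``t``."""
        if t.ndim == 0:
            return self.alpha @ expm(self.Q * float(t))
        return self.alpha @ expm_batch(self.Q[None, :, :] * t[:, None, None])

    def mean(self) -> float:
        """Expected absorption time ``-alpha @ inv(Q) @ 1``."""
        return float(-self.alpha @ np.linalg.solve(self.Q, np.ones(self.n)))

    def variance(self) -> float:
        """``2 alpha inv(Q)^2 1 - mean^2``."""
        ones = np.ones(self.n)
        qinv1 = np.linalg.solve(self.Q, ones)
        m1 = -self.alpha @ qinv1
        m2 = 2.0 * self.alpha @ np.linalg.solve(self.Q, qinv1)
        return float(m2 - m1**2)

    def cv(self) -> float:
        """Coefficient of variation sigma/mu; scale-invariant, 1 for n=1."""
        return math.sqrt(self.variance()) / self.mean()

    def hazard(self, t):
        """Instantaneous exit rate ``pdf(t) / sf(t)``.

        Returns ``nan`` where the survival probability has decayed below the
        numeric floor (the hazard is undefined there, not a number).
        """
        t = np.asarray(t, dtype=float)
        front = self._front(t)
        surv = front.sum(-1)
        dens = front @ self.q if t.ndim == 0 else (front * self.q).sum(-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(surv > SURVIVAL_FLOOR, dens / surv, np.nan)
        return float(out) if t.ndim == 0 else out

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw absorption times by simulating the phase walk.

        From phase ``i`` an ``Exp(lam_i)`` holding time elapses, then the walk
        exits with probability ``q_i / lam_i`` or moves to phase ``i + 1``.
        """
        lam = -np.diag(self.Q)
        exit_prob = self.q / lam
        out = np.zeros(size)
        # phase 1 start (Coxian canonical form); vectorised over the walk
        alive = np.arange(size)
        phase = 0
        while alive.size:
            out[alive] += rng.exponential(1.0 / lam[phase], size=alive.size)
            stay = rng.random(alive.size) >= exit_prob[phase]
            alive = alive[stay]
            phase += 1
        return out


def build_coxian(lambdas, ps) -> CoxianPH:
    """Build a Coxian PH distribution from per-phase rates and continuation
    probabilities.

    Parameters
    ----------
    lambdas : sequence of float
        Total exit rate ``lam_i > 0`` of each phase.
    ps : sequence of float
        Continuation probabilities ``p_i in (0, 1]``, one fewer than phases.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    ps = np.asarray(ps, dtype=float)
    _validate_rates(lambdas, ps)
    n = lambdas.size
    Q = np.diag(-lambdas)
    if n > 1:
        Q += np.diag(ps * lambdas[:-1], k=1)
    q = np.append((1.0 - ps) * lambdas[:-1], lambdas[-1])
    alpha = np.zeros(n)
    alpha[0] = 1.0
    return CoxianPH(alpha=alpha, Q=Q, q=q)


def _check_xyz(x: float, y: float, z: float) -> None:
    if not 0 < x <= 1:
        raise ValueError("x must lie in (0, 1]")
    if not 0 < y < 1:
        raise ValueError("y must lie in (0, 1)")
    if z < 2:
        raise ValueError("z must be >= 2")


def ph_dec(x: float, y: float, z: float) -> CoxianPH:
    """Four-phase Coxian model with strictly decreasing exit rates.

    Phase rates are ``z, 1+x, 1+x^2, x^3`` with continuation probabilities
    ``1-y, 1-y^2, 1-y^3``, so the exit-rate vector
    ``[y z, y^2 (1+x), y^3 (1+x^2), x^3]`` decreases down the phases: the
    event (speciation or extinction) becomes rarer as the lineage ages.
    Constraints: ``0 < x <= 1``, ``0 < y < 1``, ``z >= 2``.
    """
    _check_xyz(x, y, z)
    return build_coxian(
        [z, 1 + x, 1 + x**2, x**3],
        [1 - y, 1 - y**2, 1 - y**3],
    )


def ph_inc(x: float, y: float, z: float) -> CoxianPH:
    """Four-phase Coxian model with strictly increasing exit rates.

    Mirror image of :func:`ph_dec`: phase rates ``1+x^3, 1+x^2, 1+x, z`` and
    continuation probabilities ``1-y^4, 1-y^3, 1-y^2`` give the increasing
    exit-rate vector ``[y^4 (1+x^3), y^3 (1+x^2), y^2 (1+x), z]``.
    """
    _check_xyz(x, y, z)
    return build_coxian(
        [1 + x**3, 1 + x**2, 1 + x, z],
        [1 - y**4, 1 - y**3, 1 - y**2],
    )


def moments_dec(x: float, y: float, z: float) -> tuple[float, float]:
    """Closed-form first and second raw moments of the decreasing-rate model."""
    _check_xyz(x, y, z)
    m1 = 1 / z + (1 - y) * (
        1 / (1 + x) + (1 - y**2) * (1 / (1 + x**2) + (1 - y**3) / x**3)
    )
    m2 = (
        2 / z**2
        + 2 * (1 - y) / (1 + x) * (1 / z + 1 / (1 + x))
        + 2 * (1 - y) * (1 - y**2) / (1 + x**2)
        * (1 / z + 1 / (1 + x) + 1 / (1 + x**2))
        + 2 * (1 - y) * (1 - y**2) * (1 - y**3) / x**3
        * (1 / z + 1 / (1 + x) + 1 / (1 + x**2) + 1 / x**3)
    )
    return m1, m2


def moments_inc(x: float, y: float, z: float) -> tuple[float, float]:
    """Closed-form first and second raw moments of the increasing-rate model."""
    _check_xyz(x, y, z)
    m1 = 1 / (1 + x**3) + (1 - y**4) * (
        1 / (1 + x**2) + (1 - y**3) * (1 / (1 + x) + (1 - y**2) / z)
    )
    m2 = (
        2 / (1 + x**3) ** 2
        + 2 * (1 - y**4) / (1 + x**2) * (1 / (1 + x**3) + 1 / (1 + x**2))
        + 2 * (1 - y**4) * (1 - y**3) / (1 + x)
        * (1 / (1 + x**3) + 1 / (1 + x**2) + 1 / (1 + x))
        + 2 * (1 - y**4) * (1 - y**3) * (1 - y**2) / z
        * (1 / (1 + x**3) + 1 / (1 + x**2) + 1 / (1 + x) + 1 / z)
    )
    return m1, m2
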