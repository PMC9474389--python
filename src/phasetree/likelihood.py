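"""Log-likelihoods of reconstructed trees under speciation-time models.

Under symmetric speciation with no extinction, every branch of a tree is an
independent draw from the waiting-time distribution: an internal branch of
length ``b`` ended in an observed speciation (density term), while a pendant
branch of length ``b~`` reached the present without speciating (survival
term).  The tree log-likelihood is therefore a sum of density terms over
internal branches plus survival terms over pendant branches, optionally plus
``log((l-1)!)`` to count the tip orderings that map to the same edge-weight
multiset.

For the constant-rate birth-death process (rates ``lambda``, ``mu``) the
same decomposition holds once unobserved speciation-extinction excursions
are integrated out: the internal-branch factor ``G_{x}(b)`` and the
pendant-branch factor ``D(b~)`` below are closed-form solutions of the
corresponding renewal equations, and dividing by the probability that both
root lineages survive recovers the classical survival-conditioned likelihood
of Nee, May and Harvey.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln

from ._matexp import expm_batch
from .phasetype import CoxianPH
from .treesim import BranchData

__all__ = [
    "loglik_ph",
    "loglik_treeset",
    "loglik_exp",
    "loglik_weibull",
    "extinct_prob",
    "g_branch",
    "d_pendant",
    "loglik_crbd",
    "loglik_nee",
]

_LOG_FLOOR = 1e-300  # probabilities below this produce a -inf log-likelihood


def _safe_log(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    out = np.full(v.shape, -np.inf)
    ok = v > _LOG_FLOOR
    out[ok] = np.log(v[ok])
    return out


def _log_perm(n_tips: int) -> float:
    return float(gammaln(n_tips))  # log((l-1)!)


def loglik_ph(
    b: BranchData, d: CoxianPH, with_permutations: bool = False
) -> float:
    """Tree log-likelihood under phase-type speciation, no extinction.

    ``sum_i log(alpha expm(Q b_i) q) + sum_j log(alpha expm(Q b~_j) 1)``,
    plus ``log((l-1)!)`` when ``with_permutations`` is set.
    """
    lengths = np.concatenate([b.internal, b.pendant])
    fronts = d.alpha @ expm_batch(d.Q[None, :, :] * lengths[:, None, None])
    dens = fronts[: b.k] @ d.q
    surv = fronts[b.k :].sum(axis=1)
    total = _safe_log(dens).sum() + _safe_log(surv).sum()
    if with_permutations:
        total += _log_perm(b.n_tips)
    return float(total)


def loglik_treeset(
    bs, d: CoxianPH, with_permutations: bool = False
) -> float:
    """Sum of per-tree log-likelihoods over a sequence of BranchData."""
    return float(sum(loglik_ph(b, d, with_permutations) for b in bs))


def loglik_exp(b: BranchData, rate: float) -> float:
    """Exponential-speciation tree log-likelihood:
    ``k log(rate) - rate * (sum b_i + sum b~_j)``."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return float(
        b.k * math.log(rate) - rate * (b.internal.sum() + b.pendant.sum())
    )


def loglik_weibull(b: BranchData, psi: float, phi: float) -> float:
    """Weibull-speciation tree log-likelihood (``psi`` shape, ``phi`` scale).

    Internal branches contribute the Weibull density, pendant branches the
    survival function ``exp(-(b~/phi)^psi)``.
    """
    if psi <= 0 or phi <= 0:
        raise ValueError("Weibull shape and scale must be > 0")
    bi = b.internal / phi
    dens = (
        b.k * math.log(psi / phi)
        + ((psi - 1.0) * _safe_log(bi)).sum()
        - (bi**psi).sum()
    )
    surv = -((b.pendant / phi) ** psi).sum()
    return float(dens + surv)


# ---------------------------------------------------------------------------
# constant-rate birth-death (crBD)

_EQUAL_RATE_RTOL = 1e-8


def extinct_prob(z, lam: float, mu: float):
    """Probability that a lineage born at time 0 is extinct by time ``z``.

    ``E(z) = mu (1 - e^{(mu-lam) z}) / (lam - mu e^{(mu-lam) z})``; the
    critical case ``lam = mu`` uses the limit ``lam z / (1 + lam z)``.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z must be non-negative")
    if lam <= 0 or mu < 0:
        raise ValueError("need lam > 0 and mu >= 0")
    if mu == 0:
        return np.zeros_like(z) if z.ndim else 0.0
    if abs(lam - mu) < _EQUAL_RATE_RTOL * lam:
        out = lam * z / (1.0 + lam * z)
    else:
        e = np.exp((mu - lam) * z)
        out = (mu - mu * e) / (lam - mu * e)
    return out if z.ndim else float(out)


def g_branch(b, x, lam: float, mu: float):
    """Probability factor of a reconstructed internal branch of length ``b``
    whose lower end lies ``x`` before the present:

    ``G_x(b) = ((lam - mu e^{(mu-lam) x}) / (lam - mu e^{(mu-lam)(b+x)}))^2
    e^{(mu-lam) b}``.
    """
    b = np.asarray(b, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(b < 0) or np.any(x < 0):
        raise ValueError("b and x must be non-negative")
    if abs(lam - mu) < _EQUAL_RATE_RTOL * lam:
        # limit lam -> mu: ratio -> ((1 + lam x) / (1 + lam (b + x)))^2
        out = ((1.0 + lam * x) / (1.0 + lam * (b + x))) ** 2
    else:
        r = mu - lam
        out = ((lam - mu * np.exp(r * x)) / (lam - mu * np.exp(r * (b + x)))) ** 2
        out = out * np.exp(r * b)
    return out if b.ndim or np.ndim(x) else float(out)


def d_pendant(z, lam: float, mu: float):
    """Probability factor of a reconstructed pendant branch of length ``z``:

    ``D(z) = ((lam - mu) e^{mu z} / (lam - mu e^{(mu-lam) z}))^2
    e^{-(lam+mu) z}``.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z must be non-negative")
    if abs(lam - mu) < _EQUAL_RATE_RTOL * lam:
        # limit lam -> mu of the closed form
        out = (1.0 / (1.0 + lam * z)) ** 2
    else:
        r = mu - lam
        out = ((lam - mu) * np.exp(mu * z) / (lam - mu * np.exp(r * z))) ** 2
        out = out * np.exp(-(lam + mu) * z)
    return out if z.ndim else float(out)


def loglik_crbd(b: BranchData, lam: float, mu: float) -> float:
    """Reconstructed-tree log-likelihood under constant-rate birth-death.

    ``log((l-1)!) + sum_i [log G_{x_i}(b_i) + log lam]
    + sum_j log D(b~_j)``; internal branches must carry their
    elapsed-to-present times ``x_i`` (root-edge convention ``k = l - 1``).
    """
    if lam <= 0 or mu < 0:
        raise ValueError("need lam > 0 and mu >= 0")
    if b.x.size != b.k:
        raise ValueError("BranchData is missing x_i for internal branches")
    total = _log_perm(b.n_tips)
    total += _safe_log(g_branch(b.internal, b.x, lam, mu)).sum()
    total += b.k * math.log(lam)
    total += _safe_log(d_pendant(b.pendant, lam, mu)).sum()
    return float(total)


def loglik_nee(b: BranchData, lam: float, mu: float) -> float:
    """Survival-conditioned birth-death log-likelihood (Nee-May-Harvey form):
    the unconditioned log-likelihood minus ``2 log(1 - E(x_2))`` where
    ``x_2`` is the time from the origin of the root's two daughter lineages
    to the present."""
    base = loglik_crbd(b, lam, mu)
    e2 = extinct_prob(b.x2, lam, mu)
    return float(base - 2.0 * _safe_log(1.0 - e2))
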