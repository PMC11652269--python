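"""Gumbel distribution primitives and classical Karlin-Altschul score statistics.

Everything downstream uses a single parameterization of the Gumbel
(type-I extreme value) law: location ``mu`` and *rate* ``lam`` (the
reciprocal of the scale), with CDF

    F(x) = exp(-e^{-lam (x - mu)}).

Sticking to (location, rate) everywhere avoids the scale/rate confusion
between this field's convention and the ``scale`` argument of most
statistics libraries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

__all__ = [
    "GumbelParams",
    "HSPModel",
    "gumbel_density",
    "gumbel_cdf",
    "gumbel_tail",
    "gumbel_quantile",
    "sample_gumbel",
    "fit_gumbel_mle",
    "fit_gumbel_mle_batch",
    "hsp_pvalue",
    "hsp_evalue",
    "max_gumbel_location",
]

EULER_GAMMA = float(np.euler_gamma)


@dataclass(frozen=True)
class GumbelParams:
    """Location ``mu`` and rate ``lam`` (> 0) of a Gumbel law; scale = 1/lam."""

    mu: float
    lam: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu) and math.isfinite(self.lam)):
            raise ValueError("Gumbel parameters must be finite")
        if self.lam <= 0:
            raise ValueError(f"rate lam must be > 0, got {self.lam}")

    @property
    def scale(self) -> float:
        return 1.0 / self.lam

    @property
    def mean(self) -> float:
        return self.mu + EULER_GAMMA / self.lam

    @property
    def variance(self) -> float:
        return math.pi**2 / (6.0 * self.lam**2)


@dataclass(frozen=True)
class HSPModel:
    """Karlin-Altschul model for high-scoring segment pair (HSP) statistics.

    ``K`` and ``lam`` are the precomputed parameters for a given substitution
    matrix and gap penalties; ``n`` is the query length, ``l`` the subject
    length, ``L`` the total database length (sum of subject lengths) and
    ``N`` the number of database sequences.  The formulas here use the plain
    ``n*l`` search-space term; no finite-size edge correction is applied.
    """

    K: float
    lam: float
    n: int
    l: int | None = None
    L: int | None = None
    N: int | None = None

    def __post_init__(self) -> None:
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("K and lam must be > 0")
        for name in ("n", "l", "L", "N"):
            v = getattr(self, name)
            if v is not None and (int(v) != v or v < 1):
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.L is not None and self.l is not None and self.L < self.l:
            raise ValueError("total database length L must be >= subject length l")


def _check_params(p: GumbelParams) -> GumbelParams:
    if not isinstance(p, GumbelParams):
        p = GumbelParams(*p)
    return p


def gumbel_density(x, p: GumbelParams):
    """Gumbel density f(x) = lam * exp(-lam(x-mu) - e^{-lam(x-mu)})."""
    p = _check_params(p)
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    z = p.lam * (x - p.mu)
    out = p.lam * np.exp(-z - np.exp(-z))
    return out if out.ndim else float(out)


def log_gumbel_density(x, p: GumbelParams):
    """log of :func:`gumbel_density`, stable far into either tail."""
    p = _check_params(p)
    x = np.asarray(x, dtype=float)
    z = p.lam * (x - p.mu)
    out = np.log(p.lam) - z - np.exp(-z)
    return out if out.ndim else float(out)


def gumbel_cdf(x, p: GumbelParams):
    """F(x) = exp(-e^{-lam(x-mu)})."""
    p = _check_params(p)
    x = np.asarray(x, dtype=float)
    out = np.exp(-np.exp(-p.lam * (x - p.mu)))
    return out if out.ndim else float(out)


def gumbel_tail(x, p: GumbelParams):
    """Right tail P(X >= x) = 1 - F(x), computed as -expm1(-e^{-z})."""
    p = _check_params(p)
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    out = -np.expm1(-np.exp(-p.lam * (x - p.mu)))
    return out if out.ndim else float(out)


def gumbel_quantile(q, p: GumbelParams):
    """Inverse CDF: x with F(x) = q, for q in (0, 1)."""
    p = _check_params(p)
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("q must lie strictly inside (0, 1)")
    out = p.mu - np.log(-np.log(q)) / p.lam
    return out if out.ndim else float(out)


def sample_gumbel(count: int, p: GumbelParams, seed) -> np.ndarray:
    """``count`` iid Gumbel draws via inverse-CDF of uniforms.

    ``seed`` may be anything accepted by :func:`numpy.random.default_rng`
    (an int, a SeedSequence, or an existing Generator).
    """
    p = _check_params(p)
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    rng = np.random.default_rng(seed)
    u = rng.random(int(count))
    return p.mu - np.log(-np.log(u)) / p.lam


def _profile_equation(beta: float, x: np.ndarray, xbar: float) -> float:
    # beta = xbar - sum(x e^{-x/beta}) / sum(e^{-x/beta}); shift for stability
    w = np.exp(-(x - x.min()) / beta)
    return beta - xbar + float(np.dot(x, w) / w.sum())


def fit_gumbel_mle(scores) -> GumbelParams:
    """Maximum-likelihood Gumbel fit.

    The scale ``beta = 1/lam`` solves the profiled likelihood equation

        beta = mean(x) - sum_i x_i e^{-x_i/beta} / sum_i e^{-x_i/beta},

    found by bracketed root finding (xtol 1e-10 on the score scale);
    ``mu`` then follows in closed form.  Equivariant under affine maps of
    the data.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least two scores")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: the rate parameter is undefined")
    xbar = float(x.mean())
    # method-of-moments start, then expand a bracket around the root
    beta0 = float(x.std(ddof=1)) * math.sqrt(6.0) / math.pi
    lo, hi = beta0, beta0
    flo = _profile_equation(lo, x, xbar)
    fhi = flo
    for _ in range(200):
        if flo > 0:
            lo /= 2.0
            flo = _profile_equation(lo, x, xbar)
        elif fhi < 0:
            hi *= 2.0
            fhi = _profile_equation(hi, x, xbar)
        else:
            break
    else:  # pragma: no cover - pathological data
        raise RuntimeError("failed to bracket the Gumbel MLE scale")
    beta = brentq(_profile_equation, lo, hi, args=(x, xbar), xtol=1e-10)
    mu = -beta * (logsumexp(-x / beta) - math.log(x.size))
    return GumbelParams(mu=float(mu), lam=1.0 / beta)


def fit_gumbel_mle_batch(samples: np.ndarray, tol: float = 1e-12,
                         max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Gumbel MLE on a 2-D array; returns (mu, lam) arrays.

    Uses the classical fixed-point iteration on the profiled scale, which
    is monotone convergent for Gumbel likelihoods.  Intended for bulk
    simulation diagnostics where calling :func:`fit_gumbel_mle` per row
    would dominate runtime.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("samples must be 2-D with >= 2 columns")
    xbar = x.mean(axis=1)
    xmin = x.min(axis=1, keepdims=True)
    xs = x - xmin
    beta = np.maximum(x.std(axis=1, ddof=1) * math.sqrt(6.0) / math.pi, 1e-300)
    for _ in range(max_iter):
        w = np.exp(-xs / beta[:, None])
        new = xbar - np.einsum("ij,ij->i", x, w) / w.sum(axis=1)
        new = np.maximum(new, 1e-300)
        if np.all(np.abs(new - beta) <= tol * np.maximum(np.abs(new), 1.0)):
            beta = new
            break
        beta = new
    mu = -beta * (logsumexp(-x / beta[:, None], axis=1) - math.log(x.shape[1]))
    return mu, 1.0 / beta


def hsp_pvalue(s, model: HSPModel):
    """P-value of an HSP of score >= s against a single subject: 1 - exp(-K n l e^{-lam s})."""
    if model.l is None:
        raise ValueError("model.l (subject length) is required")
    s = np.asarray(s, dtype=float)
    out = -np.expm1(-model.K * model.n * model.l * np.exp(-model.lam * s))
    return out if out.ndim else float(out)


def hsp_evalue(s, model: HSPModel, *, per_sequence: bool = False):
    """Expected number of HSPs scoring >= s: K n l e^{-lam s} (one subject)
    or K n L e^{-lam s} database-wide (L = total database length)."""
    length = model.l if per_sequence else model.L
    if length is None:
        which = "l" if per_sequence else "L"
        raise ValueError(f"model.{which} is required")
    s = np.asarray(s, dtype=float)
    out = model.K * model.n * length * np.exp(-model.lam * s)
    return out if out.ndim else float(out)


def max_gumbel_location(locations, lam: float) -> float:
    """Location nu of the max of independent Gumbel(mu_i, lam) variables.

    Max-stability: the maximum is again Gumbel with the common rate and
    location nu = log(sum_i e^{lam mu_i}) / lam  >=  max(mu_i).
    """
    mus = np.asarray(locations, dtype=float)
    if mus.size == 0:
        raise ValueError("need at least one location")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    return float(logsumexp(lam * mus) / lam)
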