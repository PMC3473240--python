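"""Discrete power-law fitting for term-frequency distributions.

The frequency f of a term in an annotation corpus is modelled, above a
threshold xmin, by the discrete power law

    P(X = x) = x^-beta / zeta(beta, xmin),   x = xmin, xmin+1, ...

where zeta is the Hurwitz zeta function. The complementary cumulative
distribution P(X >= x) ~ x^-k (a Pareto form, k = beta - 1) gives a far
more stable estimate of the exponent than a rank-frequency regression,
because the CCDF is monotone and well defined at every x. The fitting
procedure is the standard maximum-likelihood one: for each candidate
xmin, estimate beta by MLE on the tail, measure the Kolmogorov-Smirnov
distance between empirical and fitted tail CCDFs, and keep the xmin
minimising it; a semi-parametric bootstrap then yields a goodness-of-fit
p-value, with p > 0.1 conventionally read as "a power law is plausible".

The Zipf rank exponent alpha (frequency ~ rank^-alpha), the frequency
exponent beta and the Pareto shape k are algebraically linked:
beta = 1 + 1/alpha, alpha = 1/k, beta = 1 + k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

#: Search interval for the exponent during maximum-likelihood estimation.
BETA_MIN = 1.0 + 1e-6
BETA_MAX = 10.0

#: Goodness-of-fit p-value above which a power law is deemed plausible.
PLAUSIBILITY_THRESHOLD = 0.1

#: Default minimum number of tail points for an xmin candidate.
DEFAULT_MIN_TAIL = 10


class EmptyTailError(ValueError):
    """No data at or above the requested xmin."""


class DegenerateTailError(ValueError):
    """All tail values are equal; the MLE for beta diverges."""


class NoCandidateError(ValueError):
    """No xmin candidate has a large enough tail."""


@dataclass(frozen=True)
class CCDF:
    """Empirical complementary CDF: p[i] = P(X >= x[i]), x ascending."""

    x: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.p) > 0):
            raise ValueError("CCDF must be non-increasing in x")


@dataclass(frozen=True)
class ZipfExponents:
    """The linked (alpha, beta, k) exponent triple.

    alpha is the Zipf rank exponent, beta the frequency power-law
    exponent, k the Pareto CCDF shape. They must satisfy
    beta = 1 + 1/alpha, alpha = 1/k and beta = 1 + k simultaneously.
    """

    alpha: float
    beta: float
    k: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.k <= 0 or self.beta <= 1:
            raise ValueError("require alpha > 0, k > 0, beta > 1")
        tol = 1e-9 * max(1.0, self.beta)
        if (
            abs(self.beta - (1 + 1 / self.alpha)) > tol
            or abs(self.alpha - 1 / self.k) > tol
            or abs(self.beta - (1 + self.k)) > tol
        ):
            raise ValueError("inconsistent (alpha, beta, k) triple")


@dataclass(frozen=True)
class PowerLawFit:
    """Result of fitting a discrete power law to a frequency sample."""

    xmin: int
    beta_hat: float
    n_tail: int
    ks_distance: float
    se: float
    min_tail: int = DEFAULT_MIN_TAIL
    p_value: float | None = None
    plausible: bool | None = None
    n_bootstrap: int | None = None
    seed: int | None = None


def _tail(values: np.ndarray, xmin: int) -> np.ndarray:
    values = np.asarray(values)
    tail = values[values >= xmin]
    if tail.size == 0:
        raise EmptyTailError(f"no values >= xmin={xmin}")
    return tail


def ccdf(values) -> CCDF:
    """Empirical CCDF of a sample of positive integers.

    p(x) = (number of values >= x) / n at every distinct observed x;
    p equals 1 at the minimum observed value.
    """
    values = np.sort(np.asarray(values))
    if values.size == 0:
        raise ValueError("cannot compute the CCDF of an empty sample")
    xs = np.unique(values)
    p = 1.0 - np.searchsorted(values, xs, side="left") / values.size
    return CCDF(x=xs, p=p)


def log_likelihood(values, beta: float, xmin: int = 1) -> float:
    """Discrete power-law log-likelihood of the tail (values >= xmin)."""
    tail = _tail(values, xmin)
    return float(-tail.size * np.log(zeta(beta, xmin)) - beta * np.log(tail).sum())


def mle_beta(values, xmin: int = 1) -> float:
    """Maximum-likelihood exponent of the discrete power-law tail.

    Maximises l(beta) = -n ln zeta(beta, xmin) - beta * sum ln x_i over
    the tail x_i >= xmin by bounded scalar search on (1, 10].

    Raises
    ------
    DegenerateTailError
        If all tail values are equal (the MLE diverges).
    EmptyTailError
        If nothing lies at or above xmin.
    """
    tail = _tail(values, xmin)
    if np.all(tail == tail[0]):
        raise DegenerateTailError("all tail values equal; MLE for beta diverges")
    n = tail.size
    log_sum = np.log(tail).sum()

    def neg_ll(beta: float) -> float:
        return n * np.log(zeta(beta, xmin)) + beta * log_sum

    res = minimize_scalar(
        neg_ll, bounds=(BETA_MIN, BETA_MAX), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def beta_standard_error(values, beta: float, xmin: int = 1) -> float:
    """Asymptotic standard error of the MLE from the Fisher information.

    The observed information is n * d^2/dbeta^2 [ln zeta(beta, xmin)],
    evaluated by central finite differences.
    """
    n = _tail(values, xmin).size
    h = 1e-4
    lz = [np.log(zeta(beta + d, xmin)) for d in (-h, 0.0, h)]
    d2 = (lz[0] - 2 * lz[1] + lz[2]) / h**2
    return float(1.0 / np.sqrt(n * d2))


def ks_distance(values, beta: float, xmin: int = 1) -> float:
    """Kolmogorov-Smirnov distance between empirical and model tail CCDFs.

    Both CCDFs are conditioned on x >= xmin; the model tail CCDF is
    zeta(beta, x) / zeta(beta, xmin). The maximum absolute difference is
    taken over every distinct observed tail value.
    """
    if beta <= 1:
        raise ValueError(f"beta must exceed 1, got {beta}")
    tail = np.sort(_tail(values, xmin))
    xs = np.unique(tail)
    emp = 1.0 - np.searchsorted(tail, xs, side="left") / tail.size
    model = zeta(beta, xs) / zeta(beta, xmin)
    return float(np.abs(emp - model).max())


def select_xmin(values, min_tail: int = DEFAULT_MIN_TAIL) -> tuple[int, float, float]:
    """Choose xmin by minimising the KS distance of the MLE fit.

    Every distinct observed value whose tail holds at least ``min_tail``
    points (and at least two distinct values, so the MLE exists) is a
    candidate; the candidate with the smallest KS distance wins, ties
    going to the smallest xmin (the largest tail).

    Returns
    -------
    (xmin, beta_hat, ks_distance)
    """
    values = np.sort(np.asarray(values))
    if values.size == 0:
        raise NoCandidateError("empty sample")
    uniq, first_idx = np.unique(values, return_index=True)
    best: tuple[int, float, float] | None = None
    for x, idx in zip(uniq, first_idx):
        n_tail = values.size - idx
        if n_tail < min_tail:
            break  # tails only shrink as xmin grows
        if uniq[uniq >= x].size < 2:
            continue
        beta = mle_beta(values[idx:], int(x))
        d = ks_distance(values[idx:], beta, int(x))
        if best is None or d < best[2]:
            best = (int(x), beta, d)
    if best is None:
        raise NoCandidateError(
            f"no xmin candidate with a tail of at least {min_tail} points"
        )
    return best


def fit_power_law(
    values,
    min_tail: int = DEFAULT_MIN_TAIL,
    n_bootstrap: int | None = None,
    seed: int | None = None,
) -> PowerLawFit:
    """Full fitting pipeline: xmin selection, MLE, optional bootstrap GOF."""
    values = np.asarray(values)
    xmin, beta, d = select_xmin(values, min_tail=min_tail)
    fit = PowerLawFit(
        xmin=xmin,
        beta_hat=beta,
        n_tail=int((values >= xmin).sum()),
        ks_distance=d,
        se=beta_standard_error(values, beta, xmin),
        min_tail=min_tail,
    )
    if n_bootstrap is not None:
        if seed is None:
            raise ValueError("a seed is required for the bootstrap p-value")
        p = gof_pvalue(values, fit, n_bootstrap=n_bootstrap, seed=seed)
        fit = PowerLawFit(
            xmin=fit.xmin, beta_hat=fit.beta_hat, n_tail=fit.n_tail,
            ks_distance=fit.ks_distance, se=fit.se, min_tail=min_tail,
            p_value=p, plausible=p > PLAUSIBILITY_THRESHOLD,
            n_bootstrap=n_bootstrap, seed=seed,
        )
    return fit


def gof_pvalue(values, fit: PowerLawFit, n_bootstrap: int = 1000,
               seed: int = 0) -> float:
    """Semi-parametric bootstrap goodness-of-fit p-value.

    Each replicate dataset has the size of the original: every point is,
    with probability n_below/n, drawn uniformly from the observed values
    below xmin, and otherwise from the fitted discrete power law at
    (beta_hat, xmin). Each replicate is refit from scratch (including
    xmin selection) and the p-value is the fraction of replicates whose
    refit KS distance is at least the observed one. Large p means the
    observed departure from a power law is unremarkable. Deterministic
    for a given seed.
    """
    from gozipf.synthetic_data import DiscretePowerLawSampler

    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be at least 1")
    values = np.asarray(values)
    n = values.size
    below = values[values < fit.xmin]
    p_below = below.size / n
    sampler = DiscretePowerLawSampler(fit.beta_hat, fit.xmin)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_bootstrap):
        from_below = rng.random(n) < p_below
        synth = np.empty(n, dtype=np.int64)
        n_below = int(from_below.sum())
        if n_below:
            synth[from_below] = rng.choice(below, size=n_below, replace=True)
        synth[~from_below] = sampler.sample(n - n_below, rng)
        try:
            _, _, d = select_xmin(synth, min_tail=fit.min_tail)
        except NoCandidateError:
            exceed += 1  # refit impossible: count as a worse fit
            continue
        if d >= fit.ks_distance:
            exceed += 1
    return exceed / n_bootstrap


def convert_exponents(
    alpha: float | None = None,
    beta: float | None = None,
    k: float | None = None,
) -> ZipfExponents:
    """Complete the (alpha, beta, k) triple from any one exponent.

    alpha is the Zipf rank exponent, beta the frequency exponent and k
    the Pareto shape; they satisfy beta = 1 + 1/alpha = 1 + k and
    alpha = 1/k.
    """
    given = [v is not None for v in (alpha, beta, k)]
    if sum(given) != 1:
        raise ValueError("exactly one of alpha, beta, k must be given")
    if alpha is not None:
        if alpha <= 0:
            raise ValueError(f"alpha must be positive, got {alpha}")
        k = 1.0 / alpha
    elif beta is not None:
        if beta <= 1:
            raise ValueError(f"beta must exceed 1, got {beta}")
        k = beta - 1.0
    assert k is not None
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    return ZipfExponents(alpha=1.0 / k, beta=1.0 + k, k=k)


def rank_frequency(table) -> np.ndarray:
    """(rank, frequency) points of a frequency table, for log-log plotting.

    This is the classic Zipf representation; no fitting is done on it —
    the exponent is estimated from the Pareto (CCDF) form instead, which
    is far less noisy in the low-frequency regime.
    """
    if len(table) == 0:
        raise ValueError("empty frequency table")
    return np.column_stack(
        [table["rank"].to_numpy(), table["frequency"].to_numpy()]
    )
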