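"""Shared posterior machinery: MCMC sampling, HDI, PSRF and ESS.

Every Bayesian model in this package (robust two-group comparison,
quantile logistic GLM) is expressed as a :class:`LogDensityModel` — an
unnormalized log posterior density over an unconstrained parameter
vector — and sampled with a multi-chain adaptive random-walk Metropolis
algorithm.  Proposal covariance and step scale are tuned during warmup
and frozen afterwards, so retained draws form a valid Markov chain with
the posterior as its stationary distribution.

Diagnostics follow the modern defaults: split-chain Gelman–Rubin
potential scale reduction factor (PSRF, a.k.a. split R-hat) and
effective sample size (ESS) via Geyer's initial-positive-sequence
truncation of the autocorrelation sum.  Highest-density intervals are
computed by the narrowest-sorted-window method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LogDensityModel",
    "PosteriorSamples",
    "PosteriorSummary",
    "ConvergenceError",
    "InitializationError",
    "hdi",
    "psrf",
    "ess",
    "sample_posterior",
    "summarize",
    "check_convergence",
]


class ConvergenceError(RuntimeError):
    """MCMC diagnostics failed; carries the partial results.

    Attributes
    ----------
    samples : PosteriorSamples
        The draws that failed the diagnostic thresholds.
    summary : pandas.DataFrame
        Per-parameter diagnostics at the time of failure.
    """

    def __init__(self, message: str, samples: "PosteriorSamples", summary: pd.DataFrame):
        super().__init__(message)
        self.samples = samples
        self.summary = summary


class InitializationError(RuntimeError):
    """Log density non-finite at an initialization point."""


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior summary for one scalar parameter: mean, 95% HDI, ESS, PSRF."""

    mean: float
    hdi_low: float
    hdi_high: float
    ess: float
    psrf: float


@dataclass(frozen=True)
class LogDensityModel:
    """A model as an unnormalized log posterior over an unconstrained vector.

    Parameters
    ----------
    names : tuple of str
        Names of the unconstrained coordinates (dimension d).
    log_density : callable
        Vectorized over rows: maps an (k, d) array of parameter vectors
        to a (k,) array of log unnormalized posterior densities.
        Constrained parameters are handled by the model through support
        transforms (e.g. log scales) with the Jacobian folded in.
    initial : callable
        ``initial(rng, k) -> (k, d)`` array of starting points.
    transform : callable, optional
        Maps an (..., d) array of unconstrained draws to a dict of named
        constrained/derived parameter arrays of shape (...,).  When
        omitted, draws are reported under ``names`` unchanged.
    """

    names: tuple
    log_density: Callable[[np.ndarray], np.ndarray]
    initial: Callable[[np.random.Generator, int], np.ndarray]
    transform: Callable[[np.ndarray], Mapping[str, np.ndarray]] | None = None


@dataclass
class PosteriorSamples:
    """Named posterior draws indexed (chain, iteration)."""

    draws: dict
    seed: int | None = None
    accept_rate: float = float("nan")
    raw: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        shapes = {np.asarray(v).shape for v in self.draws.values()}
        if len(shapes) != 1:
            raise ValueError("all parameter arrays must share (chain, iteration) shape")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError("draws must be 2-D (chain, iteration) arrays")
        for name, v in self.draws.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite draws for parameter {name!r}")

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_iterations(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    @property
    def parameters(self) -> list:
        return list(self.draws)

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated into one vector."""
        return np.asarray(self.draws[name]).reshape(-1)

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        return summarize(self, mass=mass)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format export: parameter, chain, iteration, value."""
        frames = []
        for name, arr in self.draws.items():
            m, n = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "parameter": name,
                        "chain": np.repeat(np.arange(m), n),
                        "iteration": np.tile(np.arange(n), m),
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple:
    """Highest-density interval by the narrowest-sorted-window method.

    Returns the narrowest contiguous interval containing ``ceil(mass*n)``
    of the sorted draws.  Exact for unimodal posteriors; for multimodal
    ones it returns the narrowest single interval.
    """
    x = np.sort(np.asarray(draws, dtype=float).reshape(-1))
    n = x.size
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    if n < 100:
        raise ValueError(f"need at least 100 draws for an HDI, got {n}")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def psrf(chains: np.ndarray) -> float:
    """Split-chain Gelman–Rubin potential scale reduction factor.

    Each of the m chains (rows) is split in half, giving 2m sequences;
    the statistic is sqrt(((n-1)/n * W + B/n) / W) with W the mean
    within-sequence variance and B/n the variance of sequence means.
    Values near 1 indicate the chains are sampling the same distribution.
    """
    arr = np.atleast_2d(np.asarray(chains, dtype=float))
    if arr.shape[0] < 2:
        raise ValueError("psrf requires at least 2 chains")
    n = arr.shape[1]
    if n < 100:
        raise ValueError(f"psrf requires chains of length >= 100, got {n}")
    half = n // 2
    seqs = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
    nseq = half
    within = seqs.var(axis=1, ddof=1)
    w = within.mean()
    means = seqs.mean(axis=1)
    b_over_n = means.var(ddof=1)
    if w == 0.0:
        # all sequences constant: converged degenerately
        return 1.0 if b_over_n == 0.0 else float("inf")
    var_plus = (nseq - 1) / nseq * w + b_over_n
    return float(np.sqrt(var_plus / w))


def _autocorrelation(x: np.ndarray) -> np.ndarray:
    n = x.size
    xc = x - x.mean()
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    return acov / acov[0]


def _ess_single(x: np.ndarray) -> float:
    n = x.size
    if np.ptp(x) == 0.0:
        raise ValueError("ESS undefined for a constant chain")
    rho = _autocorrelation(x)
    # Geyer initial positive sequence: sum pairs rho[2m] + rho[2m+1]
    # while they stay positive.
    tau = -1.0
    m = 0
    while 2 * m + 1 < n:
        pair = rho[2 * m] + rho[2 * m + 1]
        if pair <= 0.0:
            break
        tau += 2.0 * pair
        m += 1
    tau = max(tau, 1.0 / n)
    return float(n / tau)


def ess(draws: np.ndarray) -> float:
    """Effective sample size via initial-positive-sequence truncation.

    ESS = n / (1 + 2 * sum of autocorrelations), with the sum truncated
    at the first non-positive consecutive pair (Geyer's rule).  For a
    2-D (chain, iteration) array, per-chain values are summed.
    """
    arr = np.asarray(draws, dtype=float)
    if arr.ndim == 2:
        return float(sum(_ess_single(row) for row in arr))
    x = arr.reshape(-1)
    if x.size < 100:
        raise ValueError(f"ess requires at least 100 draws, got {x.size}")
    return _ess_single(x)


def summarize(samples: PosteriorSamples, mass: float = 0.95) -> pd.DataFrame:
    """Per-parameter mean, HDI bounds, ESS and PSRF as a DataFrame."""
    rows = []
    for name in samples.parameters:
        arr = np.asarray(samples.draws[name])
        pooled = arr.reshape(-1)
        lo, hi = hdi(pooled, mass=mass)
        try:
            e = ess(arr)
        except ValueError:
            e = float("nan")
        try:
            r = psrf(arr)
        except ValueError:
            r = float("nan")
        rows.append(
            {
                "parameter": name,
                "mean": float(pooled.mean()),
                "hdi_low": lo,
                "hdi_high": hi,
                "ess": e,
                "psrf": r,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def summary_row(samples: PosteriorSamples, name: str, mass: float = 0.95) -> PosteriorSummary:
    """One parameter's :class:`PosteriorSummary`."""
    arr = np.asarray(samples.draws[name])
    pooled = arr.reshape(-1)
    lo, hi = hdi(pooled, mass=mass)
    try:
        r = psrf(arr)
    except ValueError:
        r = float("nan")
    try:
        e = ess(arr)
    except ValueError:
        e = float("nan")
    return PosteriorSummary(float(pooled.mean()), lo, hi, e, r)


def check_convergence(
    samples: PosteriorSamples,
    psrf_max: float = 1.01,
    ess_min: float = 400.0,
) -> pd.DataFrame:
    """Verify every reported parameter meets the diagnostic thresholds.

    Raises :class:`ConvergenceError` carrying the partial results when a
    parameter has PSRF >= ``psrf_max`` or ESS <= ``ess_min``.
    """
    summ = summarize(samples)
    bad = summ[(summ["psrf"] >= psrf_max) | (summ["ess"] <= ess_min)]
    if len(bad):
        raise ConvergenceError(
            "MCMC diagnostics failed for: "
            + ", ".join(
                f"{p} (psrf={row.psrf:.4f}, ess={row.ess:.0f})" for p, row in bad.iterrows()
            ),
            samples,
            summ,
        )
    return summ


def sample_posterior(
    model: LogDensityModel,
    n_chains: int = 4,
    n_iterations: int = 10_000,
    warmup: int = 2_000,
    seed: int | None = None,
    check: bool = False,
    psrf_max: float = 1.01,
    ess_min: float = 400.0,
) -> PosteriorSamples:
    """Draw posterior samples by adaptive random-walk Metropolis.

    All chains advance in lockstep (vectorized).  During warmup the
    proposal is a multivariate normal whose covariance is re-estimated
    from the pooled, per-chain-centered warmup history and whose
    per-chain step scale is tuned toward an acceptance rate of ~0.3 by
    a Robbins–Monro recursion; both are frozen before the retained
    iterations begin.  Deterministic given ``seed``.

    With ``check=True`` the run fails with a :class:`ConvergenceError`
    diagnostics report unless every reported parameter has
    PSRF < ``psrf_max`` and ESS > ``ess_min``.
    """
    if n_chains < 2:
        raise ValueError("need at least 2 chains for convergence diagnostics")
    rng = np.random.default_rng(seed)
    d = len(model.names)
    theta = np.atleast_2d(np.asarray(model.initial(rng, n_chains), dtype=float))
    if theta.shape != (n_chains, d):
        raise ValueError(f"initial() must return shape {(n_chains, d)}, got {theta.shape}")
    lp = np.asarray(model.log_density(theta), dtype=float)
    if not np.all(np.isfinite(lp)):
        bad = theta[~np.isfinite(lp)]
        raise InitializationError(
            f"log density non-finite at initialization; offending points:\n{bad}"
        )

    target_accept = 0.3
    log_scale = np.full(n_chains, np.log(2.38 / np.sqrt(d)))
    chol = np.eye(d)
    history = np.empty((n_chains, warmup, d))
    adapt_interval = 100

    def step(theta, lp, log_scale, chol):
        z = rng.standard_normal((n_chains, d))
        prop = theta + np.exp(log_scale)[:, None] * (z @ chol.T)
        lp_prop = np.asarray(model.log_density(prop), dtype=float)
        lp_prop = np.where(np.isnan(lp_prop), -np.inf, lp_prop)
        log_u = np.log(rng.random(n_chains))
        accept = log_u < (lp_prop - lp)
        theta = np.where(accept[:, None], prop, theta)
        lp = np.where(accept, lp_prop, lp)
        return theta, lp, accept

    for it in range(warmup):
        theta, lp, accept = step(theta, lp, log_scale, chol)
        history[:, it] = theta
        # Robbins-Monro on the per-chain log step scale
        gamma = (it + 1) ** -0.6
        log_scale += gamma * (accept.astype(float) - target_accept)
        if (it + 1) % adapt_interval == 0 and it + 1 >= 2 * adapt_interval:
            lo = (it + 1) // 2  # discard the first half of history so far
            window = history[:, lo : it + 1]
            centered = window - window.mean(axis=1, keepdims=True)
            flat = centered.reshape(-1, d)
            cov = flat.T @ flat / max(flat.shape[0] - 1, 1)
            cov += 1e-10 * np.eye(d)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass  # keep the previous factor

    out = np.empty((n_chains, n_iterations, d))
    n_accept = 0
    for it in range(n_iterations):
        theta, lp, accept = step(theta, lp, log_scale, chol)
        out[:, it] = theta
        n_accept += int(accept.sum())

    if model.transform is not None:
        named = {k: np.asarray(v, dtype=float) for k, v in model.transform(out).items()}
    else:
        named = {name: out[:, :, j] for j, name in enumerate(model.names)}
    samples = PosteriorSamples(
        draws=named,
        seed=seed,
        accept_rate=n_accept / (n_chains * n_iterations),
    )
    if check:
        check_convergence(samples, psrf_max=psrf_max, ess_min=ess_min)
    return samples
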