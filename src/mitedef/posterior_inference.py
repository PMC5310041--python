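"""Derived posterior statistics and MCMC diagnostics.

Houses the virulence statistic, posterior comparisons (pMCMC), credible
interval summaries, and convergence diagnostics (Gelman-Rubin potential
scale reduction, autocorrelation, effective sample size).

Virulence
---------
With fecundity declining exponentially in mite load, a morph that retains a
fraction ``b = e^beta`` of its eggs per mite and typically carries ``I``
mites when infected loses the fraction

    V = 1 - b ** I

of its fecundity — the proportional fitness reduction given both the
morph's tolerance base ``b`` and its infection intensity ``I``.  Because
``b`` and ``I`` come from two separately fitted models, virulence draws are
built by independently resampling the two marginal posteriors (default 2000
resamples) and pairing them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "VirulenceDraws",
    "ComparisonResult",
    "compute_virulence",
    "pmcmc_compare",
    "summarize_draws",
    "gelman_rubin",
    "autocorrelation",
    "effective_sample_size",
]


@dataclass(frozen=True)
class VirulenceDraws:
    """Paired resampled draws of the virulence components for one morph."""

    morph: str
    b: np.ndarray  # per-mite fecundity retention base, e^beta
    intensity: np.ndarray  # morph infection intensity, count scale
    v: np.ndarray  # virulence, 1 - b**I

    def __post_init__(self) -> None:
        if not (self.b.shape == self.intensity.shape == self.v.shape):
            raise ValueError("component draws must be aligned")

    @property
    def resample_size(self) -> int:
        return self.v.size

    def summary(self) -> dict:
        return summarize_draws(self.v)


def compute_virulence(
    beta_draws: np.ndarray,
    intensity_draws: np.ndarray,
    resample_size: int = 2000,
    seed: int = 0,
    morph: str = "",
) -> VirulenceDraws:
    """Build virulence draws ``V = 1 - exp(beta)**I`` by independently
    resampling (with replacement) the tolerance-slope and intensity
    marginals to a common size and pairing them."""
    beta_draws = np.asarray(beta_draws, dtype=float).ravel()
    intensity_draws = np.asarray(intensity_draws, dtype=float).ravel()
    if beta_draws.size == 0 or intensity_draws.size == 0:
        raise ValueError("empty posterior draws")
    if np.any(intensity_draws < 0):
        raise ValueError("intensity draws must be non-negative")
    rng = np.random.default_rng(seed)
    b = np.exp(beta_draws[rng.integers(0, beta_draws.size, resample_size)])
    i = intensity_draws[rng.integers(0, intensity_draws.size, resample_size)]
    return VirulenceDraws(morph=morph, b=b, intensity=i, v=1.0 - b**i)


@dataclass(frozen=True)
class ComparisonResult:
    """A posterior contrast with its pMCMC."""

    label: str
    mean: float
    ci_low: float
    ci_high: float
    pmcmc: float
    convention: str


def pmcmc_compare(
    draws_x: np.ndarray,
    draws_y: Optional[np.ndarray] = None,
    convention: str = "one-sided",
    label: str = "",
    resample_size: Optional[int] = None,
    seed: int = 0,
) -> ComparisonResult:
    """pMCMC for the contrast ``x - y`` (or ``x`` against zero).

    The pMCMC is the proportion of draws whose sign opposes the sign of the
    posterior mean difference, floored at ``1/n`` (one can never observe a
    tail proportion of exactly zero from a finite sample).  The draws are
    paired; unequal-length inputs must be put on a common footing first by
    passing ``resample_size``, which independently resamples both marginals
    (the rule used for quantities estimated in separate models).  With
    ``convention="two-sided"`` the proportion is doubled (capped at 1).
    """
    x = np.asarray(draws_x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty draws")
    y = (
        np.zeros_like(x)
        if draws_y is None
        else np.asarray(draws_y, dtype=float).ravel()
    )
    if y.size == 0:
        raise ValueError("empty draws")
    if resample_size is not None:
        rng = np.random.default_rng(seed)
        x = x[rng.integers(0, x.size, resample_size)]
        y = y[rng.integers(0, y.size, resample_size)]
    elif x.size != y.size:
        raise ValueError(
            "unequal draw counts: pass resample_size to pair by resampling"
        )
    d = x - y
    n = d.size
    m = d.mean()
    opposing = np.count_nonzero(d < 0) if m > 0 else np.count_nonzero(d > 0)
    p = max(opposing / n, 1.0 / n)
    if convention == "two-sided":
        p = min(2.0 * p, 1.0)
    elif convention != "one-sided":
        raise ValueError(f"unknown convention {convention!r}")
    lo, hi = np.percentile(d, [2.5, 97.5])
    return ComparisonResult(
        label=label, mean=float(m), ci_low=float(lo), ci_high=float(hi),
        pmcmc=float(p), convention=convention,
    )


def summarize_draws(draws: np.ndarray) -> dict:
    """Posterior mean with central 95% credible interval (empirical 2.5th
    and 97.5th percentiles)."""
    d = np.asarray(draws, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty draws")
    lo, hi = np.percentile(d, [2.5, 97.5])
    return {"mean": float(d.mean()), "ci_low": float(lo), "ci_high": float(hi)}


def gelman_rubin(chains) -> float:
    """Classical potential scale reduction factor R-hat.

    ``chains`` is an array-like of m >= 2 equal-length draw sequences.  With
    within-chain variance W and between-chain variance B (of the chain
    means, times n), R-hat = sqrt(((n-1)/n * W + (1 + 1/m) * B/n) / W).
    Values near 1 indicate convergence.
    """
    arr = np.asarray([np.asarray(c, dtype=float) for c in chains])
    if arr.ndim != 2:
        raise ValueError("chains must be equal-length sequences")
    m, n = arr.shape
    if m < 2 or n < 2:
        raise ValueError("need at least two chains of length >= 2")
    w = arr.var(axis=1, ddof=1).mean()
    b_over_n = arr.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b_over_n == 0 else float("inf")
    var_hat = (n - 1) / n * w + (1.0 + 1.0 / m) * b_over_n
    return float(np.sqrt(var_hat / w))


def autocorrelation(draws: np.ndarray, lag: int) -> float:
    """Sample autocorrelation at the given lag.

    Constant sequences are degenerate: defined as 0 with a warning.
    """
    d = np.asarray(draws, dtype=float).ravel()
    if lag < 0 or lag >= d.size:
        raise ValueError("lag must satisfy 0 <= lag < len(draws)")
    c = d - d.mean()
    denom = np.dot(c, c)
    if denom == 0:
        warnings.warn("constant draws: autocorrelation undefined, returning 0",
                      stacklevel=2)
        return 0.0
    if lag == 0:
        return 1.0
    return float(np.dot(c[:-lag], c[lag:]) / denom)


def effective_sample_size(draws: np.ndarray) -> float:
    """Effective sample size by the initial-positive-sequence estimator:
    ``n / (1 + 2 * sum rho_k)`` where the sum runs over pairs of adjacent
    autocorrelations while the pair sums stay positive."""
    d = np.asarray(draws, dtype=float).ravel()
    n = d.size
    if n < 2:
        raise ValueError("need at least two draws")
    c = d - d.mean()
    if np.dot(c, c) == 0:
        warnings.warn("constant draws: treating as independent", stacklevel=2)
        return float(n)
    # FFT autocovariances
    fsize = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(c, fsize)
    acov = np.fft.irfft(f * np.conjugate(f), fsize)[:n] / n
    rho = acov / acov[0]
    s = 0.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        s += pair
        k += 2
    return float(min(n, n / (1.0 + 2.0 * s)))
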