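"""Random-slope Poisson GLMM for fecundity tolerance.

Egg counts of mated females decline log-linearly with mite load,

    eggs ~ Poisson(exp(alpha_morph + (beta_morph + s_g) * mites + u_g + eps)),

with morph-specific intercepts and per-mite slopes, correlated group
(population-by-year) intercept/slope deviations ``(u_g, s_g)`` drawn from an
unstructured 2x2 covariance, and additive log-normal over-dispersion
``eps``.  Tolerance is the slope: a flatter (less negative) ``beta`` means
the morph loses less fecundity per mite.  Mite load enters raw (uncentred),
so the intercept is fecundity in the absence of parasites.

Only the two common female morphs (A, I) are fitted by default; the rare O
morph can be forced in with ``allow_rare_morphs`` but its reaction norm is
poorly identified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._mcmc import MCMCSchedule, PriorSettings, run_tolerance_chains
from .data_model import Phenotype, SurveyRecord, records_to_frame
from .posterior_inference import pmcmc_compare, summarize_draws

__all__ = [
    "ToleranceModelSpec",
    "TolerancePosterior",
    "fit_tolerance",
    "percent_decrease_per_mite",
    "intercept_contrast",
    "predict_fecundity",
    "variance_partition",
]


@dataclass(frozen=True)
class ToleranceModelSpec:
    """Model structure and prior settings for the tolerance fit."""

    morphs: tuple = ("A", "I")
    priors: PriorSettings = field(default_factory=PriorSettings)
    #: half-t scale for the group intercept/slope standard deviations; kept
    #: tighter than the residual scale because group heterogeneity on the
    #: log-egg scale is modest
    group_sd_scale: float = 1.0
    allow_rare_morphs: bool = False


@dataclass
class TolerancePosterior:
    """Posterior draws from the tolerance model, shaped ``(chains, draws)``
    with a trailing morph axis on the fixed effects."""

    morphs: tuple
    alpha: np.ndarray  # (C, D, M) log-scale intercepts
    beta: np.ndarray  # (C, D, M) per-mite log-scale slopes
    sigma2_u0: np.ndarray  # group intercept variance
    cov_u01: np.ndarray  # group intercept-slope covariance
    sigma2_u1: np.ndarray  # group slope variance
    sigma2_eps: np.ndarray  # unit over-dispersion variance
    schedule: MCMCSchedule = None
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(self.sigma2_eps <= 0):
            raise ValueError("sigma2_eps draws must be strictly positive")
        det = self.sigma2_u0 * self.sigma2_u1 - self.cov_u01**2
        if np.any(det < -1e-12) or np.any(self.sigma2_u0 < 0) or np.any(self.sigma2_u1 < 0):
            raise ValueError("random-effect covariance draws must be PSD")

    def morph_index(self, morph) -> int:
        code = morph.value if isinstance(morph, Phenotype) else str(morph)
        return self.morphs.index(code)

    def beta_draws(self, morph) -> np.ndarray:
        return self.beta[:, :, self.morph_index(morph)].ravel()

    def alpha_draws(self, morph) -> np.ndarray:
        return self.alpha[:, :, self.morph_index(morph)].ravel()

    def to_frame(self) -> pd.DataFrame:
        C, D, M = self.alpha.shape
        cols = {
            "chain": np.repeat(np.arange(C), D),
            "draw": np.tile(np.arange(D), C),
        }
        for m, code in enumerate(self.morphs):
            cols[f"alpha_{code}"] = self.alpha[:, :, m].ravel()
        for m, code in enumerate(self.morphs):
            cols[f"beta_{code}"] = self.beta[:, :, m].ravel()
        cols["sigma2_u0"] = self.sigma2_u0.ravel()
        cols["cov_u01"] = self.cov_u01.ravel()
        cols["sigma2_u1"] = self.sigma2_u1.ravel()
        cols["sigma2_eps"] = self.sigma2_eps.ravel()
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TolerancePosterior":
        codes = [c[6:] for c in frame.columns if c.startswith("alpha_")]
        C = int(frame["chain"].max()) + 1
        D = len(frame) // C

        def grab(prefix):
            return np.stack(
                [frame[f"{prefix}_{c}"].to_numpy().reshape(C, D) for c in codes], axis=-1
            )

        return cls(
            morphs=tuple(codes),
            alpha=grab("alpha"),
            beta=grab("beta"),
            sigma2_u0=frame["sigma2_u0"].to_numpy().reshape(C, D),
            cov_u01=frame["cov_u01"].to_numpy().reshape(C, D),
            sigma2_u1=frame["sigma2_u1"].to_numpy().reshape(C, D),
            sigma2_eps=frame["sigma2_eps"].to_numpy().reshape(C, D),
        )


def fit_tolerance(
    records: Sequence[SurveyRecord],
    spec: Optional[ToleranceModelSpec] = None,
    mcmc: Optional[MCMCSchedule] = None,
    seed: int = 0,
) -> TolerancePosterior:
    """Fit the fecundity-tolerance GLMM to mated females with egg counts."""
    spec = spec or ToleranceModelSpec()
    mcmc = mcmc or MCMCSchedule.reduced()
    if spec.allow_rare_morphs and "O" not in spec.morphs:
        spec = ToleranceModelSpec(
            morphs=spec.morphs + ("O",),
            priors=spec.priors,
            group_sd_scale=spec.group_sd_scale,
            allow_rare_morphs=True,
        )
        warnings.warn(
            "fitting the rare O morph: its reaction norm is typically unstable",
            stacklevel=2,
        )
    frame = records_to_frame(list(records))
    frame = frame[
        frame["mated"]
        & frame["eggs"].notna()
        & frame["phenotype"].isin(spec.morphs)
    ]
    present = [m for m in spec.morphs if m in set(frame["phenotype"])]
    if len(present) < 2:
        raise ValueError(
            "slope contrast undefined: need at least two morphs with fecundity data"
        )
    groups = sorted(set(zip(frame["population"], frame["year"])))
    if len(groups) < 2:
        raise ValueError("need at least two population-by-year groups")
    gmap = {g: i for i, g in enumerate(groups)}
    mmap = {c: i for i, c in enumerate(present)}
    draws = run_tolerance_chains(
        eggs=frame["eggs"].to_numpy(),
        mites=frame["mites"].to_numpy(),
        morph_idx=frame["phenotype"].map(mmap).to_numpy(),
        group_idx=np.array([gmap[g] for g in zip(frame["population"], frame["year"])]),
        n_group=len(groups),
        priors=spec.priors,
        group_sd_scale=spec.group_sd_scale,
        schedule=mcmc,
        seed=seed,
    )
    return TolerancePosterior(
        morphs=tuple(present),
        alpha=draws["alpha"],
        beta=draws["beta"],
        sigma2_u0=draws["sigma2_u0"],
        cov_u01=draws["cov_u01"],
        sigma2_u1=draws["sigma2_u1"],
        sigma2_eps=draws["sigma2_eps"],
        schedule=mcmc,
        seed=seed,
    )


def percent_decrease_per_mite(beta_draws: np.ndarray) -> dict:
    """Per-mite percent fecundity loss, ``(1 - e^beta) * 100``.

    Positive values mean fecundity loss.  Returns mean and central 95%
    credible interval of the draw-wise transform.
    """
    beta_draws = np.asarray(beta_draws, dtype=float)
    if not np.all(np.isfinite(beta_draws)):
        raise ValueError("slope draws must be finite")
    pct = (1.0 - np.exp(beta_draws)) * 100.0
    return summarize_draws(pct)


def intercept_contrast(
    post: TolerancePosterior,
    morph_a: str = "I",
    morph_b: str = "A",
    convention: str = "one-sided",
) -> dict:
    """Morph contrast of fecundity at zero mites.

    Returns summaries of (i) ``exp(alpha_a) - exp(alpha_b)`` on the egg
    scale and (ii) the ratio ``exp(alpha_a - alpha_b)``, each with a pMCMC
    for the difference.
    """
    da = post.alpha_draws(morph_a)
    db = post.alpha_draws(morph_b)
    diff = np.exp(da) - np.exp(db)
    ratio = np.exp(da - db)
    cmp_ = pmcmc_compare(np.exp(da), np.exp(db), convention=convention,
                         label=f"intercept {morph_a} vs {morph_b}")
    return {
        "difference": summarize_draws(diff),
        "ratio": summarize_draws(ratio),
        "pmcmc": cmp_.pmcmc,
        "convention": cmp_.convention,
    }


def predict_fecundity(
    post: TolerancePosterior,
    morph,
    mite_grid: Sequence[int] = range(0, 57),
) -> pd.DataFrame:
    """Fitted reaction norm: draw-wise ``exp(alpha + beta * m)`` over a grid
    of mite loads, summarised as posterior mean and central 95% band."""
    grid = np.asarray(list(mite_grid))
    if np.any(grid < 0):
        raise ValueError("mite grid must be non-negative")
    a = post.alpha_draws(morph)[:, None]
    b = post.beta_draws(morph)[:, None]
    pred = np.exp(a + b * grid[None, :])
    lo, hi = np.percentile(pred, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"mites": grid, "mean": pred.mean(axis=0), "ci_low": lo, "ci_high": hi}
    )


def variance_partition(post, process: Optional[str] = None) -> dict:
    """Share of latent (link-scale) variance attributable to the
    population-by-year random effect: ``sigma2_group / (sigma2_group +
    sigma2_residual)``, summarised draw-wise.

    For a resistance posterior pass ``process`` = ``"logit"`` (prevalence)
    or ``"log"`` (intensity); for a tolerance posterior the partition is
    group-intercept variance against unit over-dispersion.  Only latent
    variances enter — no link-distribution variance term is added.
    """
    if process in ("logit", "log"):
        if process == "logit":
            g = np.asarray(post.sigma2_g_logit, dtype=float).ravel()
            e = np.full_like(g, float(post.sigma2_e_logit))
        else:
            g = np.asarray(post.sigma2_g_log, dtype=float).ravel()
            e = np.asarray(post.sigma2_e_log, dtype=float).ravel()
    elif process is None:
        g = np.asarray(post.sigma2_u0, dtype=float).ravel()
        e = np.asarray(post.sigma2_eps, dtype=float).ravel()
    else:
        raise ValueError(f"unknown process {process!r}")
    return summarize_draws(g / (g + e))
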