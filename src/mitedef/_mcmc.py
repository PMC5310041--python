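"""Blocked adaptive Metropolis-within-Gibbs samplers.

Both hierarchical models are sampled with the same machinery:

* scalar parameters and conditionally independent blocks (phenotype effects,
  group effects, unit-level over-dispersion effects) take vectorised
  random-walk Metropolis steps with Robbins-Monro step-size adaptation
  during burn-in (target acceptance 0.44, frozen afterwards);
* each variance component is updated twice per sweep — once in the centred
  parameterisation (conditioning on the realised effects) and once in the
  non-centred one (conditioning on the standardised effects), the classic
  interweaving strategy that keeps scale parameters mobile whether or not
  the individual effects are well identified;
* exact translation moves shift a fixed-effect level against the mean of the
  random effects it is confounded with (the likelihood is invariant, only
  priors change), removing the slow ridge walk along that direction.

The hurdle (logit) process carries a unit-level over-dispersion effect whose
variance is not identifiable from binary data; it is held fixed and
marginalised out of the Bernoulli likelihood by Gauss-Hermite quadrature.
All other unit effects are sampled as latent parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import special

__all__ = ["MCMCSchedule", "PriorSettings", "run_resistance_chains", "run_tolerance_chains"]


@dataclass(frozen=True)
class MCMCSchedule:
    """Iteration schedule for one fit.

    ``draws`` posterior samples are kept per chain after ``burn_in``
    adaptation sweeps, saving every ``thin``-th sweep.
    """

    chains: int = 2
    draws: int = 1000
    burn_in: int = 1500
    thin: int = 2

    @property
    def iterations(self) -> int:
        return self.burn_in + self.draws * self.thin

    @classmethod
    def reduced(cls) -> "MCMCSchedule":
        """Desk-scale default."""
        return cls()

    @classmethod
    def paper(cls) -> "MCMCSchedule":
        """The published schedule: 2 000 000 post-burn-in iterations after a
        100 000-iteration burn-in, saving every 1000th sweep (2000 draws)."""
        return cls(chains=1, draws=2000, burn_in=100_000, thin=1000)

    def validate(self) -> None:
        if self.chains < 1 or self.draws < 2 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("invalid MCMC schedule")


@dataclass(frozen=True)
class PriorSettings:
    """Weakly-informative default priors.

    Fixed effects get Normal(0, ``fixed_effect_sd``^2); standard deviations
    get half-Student-t(``sd_df``, ``sd_scale``); correlations are uniform on
    (-1, 1).
    """

    fixed_effect_sd: float = 10.0
    sd_df: float = 3.0
    sd_scale: float = 2.0


def _half_t_logpdf(sigma: float, df: float, scale: float) -> float:
    # unnormalised; sigma > 0
    return -0.5 * (df + 1.0) * math.log1p((sigma / scale) ** 2 / df)


class _StepSize:
    """Robbins-Monro adapted random-walk scales (vectorised)."""

    def __init__(self, shape, init=0.3, target=0.44):
        self.log_s = np.full(shape, math.log(init))
        self.target = target
        self.t = 0
        self.frozen = False

    @property
    def s(self):
        return np.exp(self.log_s)

    def update(self, accepted):
        if self.frozen:
            return
        self.t += 1
        gamma = min(0.5, 2.0 / self.t**0.6)
        self.log_s += gamma * (np.asarray(accepted, dtype=float) - self.target)
        np.clip(self.log_s, -12.0, 4.0, out=self.log_s)


def _accept(rng, logr):
    logr = np.asarray(logr, dtype=float)
    return np.log(rng.uniform(size=logr.shape)) < logr


# ---------------------------------------------------------------------------
# resistance: zero-altered Poisson with phenotype effects and group effects
# on both processes
# ---------------------------------------------------------------------------

def run_resistance_chains(
    y: np.ndarray,
    pheno_idx: np.ndarray,
    group_idx: np.ndarray,
    n_pheno: int,
    n_group: int,
    sigma2_unit_logit: float,
    priors: PriorSettings,
    schedule: MCMCSchedule,
    seed: int,
) -> dict:
    """Sample the hurdle-Poisson posterior; returns draw arrays keyed by name,
    each of shape ``(chains, draws, ...)``."""
    schedule.validate()
    y = np.asarray(y, dtype=np.int64)
    z = y > 0
    inf = np.flatnonzero(z)
    yk = y[inf].astype(float)
    pk = pheno_idx[inf]
    gk = group_idx[inf]
    n = y.size
    n_inf = inf.size

    # The marginal Bernoulli probability E[inv-logit(mu + sd*Z)] is a fixed
    # smooth monotone function of mu (sd is held constant), so its log and
    # complementary log are tabulated once on a fine grid and interpolated.
    gx, gw = hermegauss(41)
    gw = gw / gw.sum()
    offs = math.sqrt(sigma2_unit_logit) * gx  # (K,)
    grid = np.arange(-30.0, 30.0 + 1e-9, 0.005)
    pg = special.expit(grid[:, None] + offs[None, :]) @ gw
    np.clip(pg, 1e-300, 1.0 - 1e-16, out=pg)
    log_p_tab = np.log(pg)
    log_q_tab = np.log1p(-pg)

    fe_var = priors.fixed_effect_sd**2

    def bern_ll(mu):
        mu = np.clip(mu, -30.0, 30.0)
        return np.where(
            z, np.interp(mu, grid, log_p_tab), np.interp(mu, grid, log_q_tab)
        )

    def ztp_ll(mu2):
        mu2 = np.clip(mu2, -30.0, 30.0)
        lam = np.exp(mu2)
        return yk * mu2 - lam - np.log(-np.expm1(-lam))

    def sd_lp(s):
        return _half_t_logpdf(s, priors.sd_df, priors.sd_scale)

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(schedule.chains)

    # empirical starting points
    prev = np.bincount(pheno_idx, weights=z.astype(float), minlength=n_pheno)
    prev /= np.maximum(np.bincount(pheno_idx, minlength=n_pheno), 1)
    zeta0 = special.logit(np.clip(prev, 0.01, 0.99))
    mean_k = np.ones(n_pheno)
    for p in range(n_pheno):
        sel = yk[pk == p]
        if sel.size:
            mean_k[p] = max(sel.mean(), 1.05)
    eta0 = np.log(mean_k - 1.0 + 1e-6)  # rough ZTP rate guess

    out = {
        "zeta": np.empty((schedule.chains, schedule.draws, n_pheno)),
        "eta": np.empty((schedule.chains, schedule.draws, n_pheno)),
        "sigma2_g_logit": np.empty((schedule.chains, schedule.draws)),
        "sigma2_g_log": np.empty((schedule.chains, schedule.draws)),
        "sigma2_e_log": np.empty((schedule.chains, schedule.draws)),
    }

    for ci, cs in enumerate(chain_seeds):
        rng = np.random.default_rng(cs)
        zeta = zeta0 + rng.normal(0, 0.3, n_pheno)
        eta = eta0 + rng.normal(0, 0.3, n_pheno)
        a = np.zeros(n_group)
        b = np.zeros(n_group)
        e2 = np.zeros(n_inf)
        ls_ga = math.log(0.8) + rng.normal(0, 0.2)
        ls_gb = math.log(0.3) + rng.normal(0, 0.2)
        ls_e2 = math.log(0.4) + rng.normal(0, 0.2)

        st_zeta = _StepSize(n_pheno, 0.1)
        st_a = _StepSize(n_group, 0.3)
        st_eta = _StepSize(n_pheno, 0.1)
        st_b = _StepSize(n_group, 0.2)
        st_e2 = _StepSize(n_inf, 0.5)
        st_sga = _StepSize((), 0.3)
        st_sga_nc = _StepSize((), 0.15)
        st_sgb = _StepSize((), 0.3)
        st_sgb_nc = _StepSize((), 0.15)
        st_se2 = _StepSize((), 0.1)
        st_se2_nc = _StepSize((), 0.1)
        st_tza = _StepSize((), 0.2)
        st_teb = _StepSize((), 0.1)
        st_tee = _StepSize(n_pheno, 0.1)
        st_tbe = _StepSize(n_group, 0.1)
        steps = [
            st_zeta, st_a, st_eta, st_b, st_e2, st_sga, st_sga_nc, st_sgb,
            st_sgb_nc, st_se2, st_se2_nc, st_tza, st_teb, st_tee, st_tbe,
        ]

        kept = 0
        mu = zeta[pheno_idx] + a[group_idx]
        ll = bern_ll(mu)
        for it in range(schedule.iterations):
            if it == schedule.burn_in:
                for s in steps:
                    s.frozen = True

            # ---- hurdle process ----
            # phenotype effects (conditionally independent across levels)
            dz = st_zeta.s * rng.standard_normal(n_pheno)
            ll_new = bern_ll(mu + dz[pheno_idx])
            logr = (
                np.bincount(pheno_idx, ll_new, n_pheno)
                - np.bincount(pheno_idx, ll, n_pheno)
                - ((zeta + dz) ** 2 - zeta**2) / (2 * fe_var)
            )
            acc = _accept(rng, logr)
            st_zeta.update(acc)
            if acc.any():
                zeta = zeta + dz * acc
                mu = mu + (dz * acc)[pheno_idx]
                ll = np.where(acc[pheno_idx], ll_new, ll)

            # group effects
            s_ga = math.exp(ls_ga)
            da = st_a.s * rng.standard_normal(n_group)
            ll_new = bern_ll(mu + da[group_idx])
            logr = (
                np.bincount(group_idx, ll_new, n_group)
                - np.bincount(group_idx, ll, n_group)
                - ((a + da) ** 2 - a**2) / (2 * s_ga**2)
            )
            acc = _accept(rng, logr)
            st_a.update(acc)
            if acc.any():
                a = a + da * acc
                mu = mu + (da * acc)[group_idx]
                ll = np.where(acc[group_idx], ll_new, ll)

            # translation: level of zeta against mean of a (likelihood invariant)
            d = st_tza.s * rng.standard_normal()
            logr = (
                -(((zeta + d) ** 2 - zeta**2).sum()) / (2 * fe_var)
                - (((a - d) ** 2 - a**2).sum()) / (2 * s_ga**2)
            )
            acc = _accept(rng, logr)
            st_tza.update(acc)
            if acc:
                zeta = zeta + d
                a = a - d

            # group sd, centred then non-centred (interweaving)
            lsp = ls_ga + st_sga.s * rng.standard_normal()
            sp = math.exp(lsp)
            logr = (
                -n_group * (lsp - ls_ga)
                - (a**2).sum() / 2 * (1 / sp**2 - 1 / s_ga**2)
                + sd_lp(sp) - sd_lp(s_ga) + (lsp - ls_ga)
            )
            acc = _accept(rng, logr)
            st_sga.update(acc)
            if acc:
                ls_ga = lsp
            s_ga = math.exp(ls_ga)
            a_std = a / s_ga
            lsp = ls_ga + st_sga_nc.s * rng.standard_normal()
            sp = math.exp(lsp)
            mu_new = zeta[pheno_idx] + (sp * a_std)[group_idx]
            ll_new = bern_ll(mu_new)
            logr = (
                ll_new.sum() - ll.sum()
                + sd_lp(sp) - sd_lp(s_ga) + (lsp - ls_ga)
            )
            acc = _accept(rng, logr)
            st_sga_nc.update(acc)
            if acc:
                ls_ga = lsp
                a = sp * a_std
                mu = mu_new
                ll = ll_new

            # ---- zero-truncated count process (infected records only) ----
            if n_inf:
                mu2 = eta[pk] + b[gk] + e2
                ll2 = ztp_ll(mu2)

                de = st_eta.s * rng.standard_normal(n_pheno)
                ll2_new = ztp_ll(mu2 + de[pk])
                logr = (
                    np.bincount(pk, ll2_new, n_pheno)
                    - np.bincount(pk, ll2, n_pheno)
                    - ((eta + de) ** 2 - eta**2) / (2 * fe_var)
                )
                acc = _accept(rng, logr)
                st_eta.update(acc)
                if acc.any():
                    eta = eta + de * acc
                    mu2 = mu2 + (de * acc)[pk]
                    ll2 = np.where(acc[pk], ll2_new, ll2)

                s_gb = math.exp(ls_gb)
                db = st_b.s * rng.standard_normal(n_group)
                ll2_new = ztp_ll(mu2 + db[gk])
                logr = (
                    np.bincount(gk, ll2_new, n_group)
                    - np.bincount(gk, ll2, n_group)
                    - ((b + db) ** 2 - b**2) / (2 * s_gb**2)
                )
                acc = _accept(rng, logr)
                st_b.update(acc)
                if acc.any():
                    b = b + db * acc
                    mu2 = mu2 + (db * acc)[gk]
                    ll2 = np.where(acc[gk], ll2_new, ll2)

                # unit over-dispersion effects
                s_e2 = math.exp(ls_e2)
                dd = st_e2.s * rng.standard_normal(n_inf)
                ll2_new = ztp_ll(mu2 + dd)
                logr = ll2_new - ll2 - ((e2 + dd) ** 2 - e2**2) / (2 * s_e2**2)
                acc = _accept(rng, logr)
                st_e2.update(acc)
                if acc.any():
                    e2 = np.where(acc, e2 + dd, e2)
                    mu2 = np.where(acc, mu2 + dd, mu2)

                # translations along confounded directions: eta level vs
                # group effects; per-phenotype eta vs unit effects; per-group
                # b vs unit effects (likelihood invariant, priors only)
                d = st_teb.s * rng.standard_normal()
                logr = (
                    -(((eta + d) ** 2 - eta**2).sum()) / (2 * fe_var)
                    - (((b - d) ** 2 - b**2).sum()) / (2 * s_gb**2)
                )
                acc = _accept(rng, logr)
                st_teb.update(acc)
                if acc:
                    eta = eta + d
                    b = b - d
                dp = st_tee.s * rng.standard_normal(n_pheno)
                de2 = dp[pk]
                dprior = ((e2 - de2) ** 2 - e2**2) / (2 * s_e2**2)
                logr = (
                    -((eta + dp) ** 2 - eta**2) / (2 * fe_var)
                    - np.bincount(pk, dprior, n_pheno)
                )
                acc = _accept(rng, logr)
                st_tee.update(acc)
                if acc.any():
                    eta = eta + dp * acc
                    e2 = e2 - de2 * acc[pk]
                dg = st_tbe.s * rng.standard_normal(n_group)
                de2 = dg[gk]
                dprior = ((e2 - de2) ** 2 - e2**2) / (2 * s_e2**2)
                logr = (
                    -(((b + dg) ** 2 - b**2)) / (2 * s_gb**2)
                    - np.bincount(gk, dprior, n_group)
                )
                acc = _accept(rng, logr)
                st_tbe.update(acc)
                if acc.any():
                    b = b + dg * acc
                    e2 = e2 - de2 * acc[gk]

                # count-process group sd (interweaving)
                s_gb = math.exp(ls_gb)
                lsp = ls_gb + st_sgb.s * rng.standard_normal()
                sp = math.exp(lsp)
                logr = (
                    -n_group * (lsp - ls_gb)
                    - (b**2).sum() / 2 * (1 / sp**2 - 1 / s_gb**2)
                    + sd_lp(sp) - sd_lp(s_gb) + (lsp - ls_gb)
                )
                acc = _accept(rng, logr)
                st_sgb.update(acc)
                if acc:
                    ls_gb = lsp
                s_gb = math.exp(ls_gb)
                b_std = b / s_gb
                lsp = ls_gb + st_sgb_nc.s * rng.standard_normal()
                sp = math.exp(lsp)
                mu2_cur = eta[pk] + b[gk] + e2
                mu2_new = eta[pk] + (sp * b_std)[gk] + e2
                logr = (
                    ztp_ll(mu2_new).sum() - ztp_ll(mu2_cur).sum()
                    + sd_lp(sp) - sd_lp(s_gb) + (lsp - ls_gb)
                )
                acc = _accept(rng, logr)
                st_sgb_nc.update(acc)
                if acc:
                    ls_gb = lsp
                    b = sp * b_std

                # unit over-dispersion sd (interweaving)
                s_e2 = math.exp(ls_e2)
                lsp = ls_e2 + st_se2.s * rng.standard_normal()
                sp = math.exp(lsp)
                logr = (
                    -n_inf * (lsp - ls_e2)
                    - (e2**2).sum() / 2 * (1 / sp**2 - 1 / s_e2**2)
                    + sd_lp(sp) - sd_lp(s_e2) + (lsp - ls_e2)
                )
                acc = _accept(rng, logr)
                st_se2.update(acc)
                if acc:
                    ls_e2 = lsp
                s_e2 = math.exp(ls_e2)
                e2_std = e2 / s_e2
                lsp = ls_e2 + st_se2_nc.s * rng.standard_normal()
                sp = math.exp(lsp)
                mu2_cur = eta[pk] + b[gk] + e2
                mu2_new = eta[pk] + b[gk] + sp * e2_std
                logr = (
                    ztp_ll(mu2_new).sum() - ztp_ll(mu2_cur).sum()
                    + sd_lp(sp) - sd_lp(s_e2) + (lsp - ls_e2)
                )
                acc = _accept(rng, logr)
                st_se2_nc.update(acc)
                if acc:
                    ls_e2 = lsp
                    e2 = sp * e2_std

            post = it - schedule.burn_in
            if post >= 0 and (post + 1) % schedule.thin == 0 and kept < schedule.draws:
                out["zeta"][ci, kept] = zeta
                out["eta"][ci, kept] = eta
                out["sigma2_g_logit"][ci, kept] = math.exp(2 * ls_ga)
                out["sigma2_g_log"][ci, kept] = math.exp(2 * ls_gb)
                out["sigma2_e_log"][ci, kept] = math.exp(2 * ls_e2)
                kept += 1

    return out


# ---------------------------------------------------------------------------
# tolerance: Poisson GLMM with morph intercepts/slopes and correlated group
# intercepts/slopes
# ---------------------------------------------------------------------------

def _bvn_ll(u, v, s0, s1, rho):
    om = 1.0 - rho**2
    q = (u / s0) ** 2 - 2 * rho * (u / s0) * (v / s1) + (v / s1) ** 2
    return -math.log(s0 * s1) - 0.5 * math.log(om) - 0.5 * q / om


def run_tolerance_chains(
    eggs: np.ndarray,
    mites: np.ndarray,
    morph_idx: np.ndarray,
    group_idx: np.ndarray,
    n_group: int,
    priors: PriorSettings,
    group_sd_scale: float,
    schedule: MCMCSchedule,
    seed: int,
) -> dict:
    """Sample the random-slope Poisson GLMM posterior.

    ``group_sd_scale`` is the half-t scale for the group intercept/slope
    standard deviations (the residual sd keeps ``priors.sd_scale``).
    """
    schedule.validate()
    yk = np.asarray(eggs, dtype=float)
    x = np.asarray(mites, dtype=float)
    n = yk.size
    n_morph = int(morph_idx.max()) + 1 if n else 2

    fe_var = priors.fixed_effect_sd**2

    def pois_ll(mu):
        mu = np.clip(mu, -30.0, 30.0)
        return yk * mu - np.exp(mu)

    def sd_lp(s, scale):
        return _half_t_logpdf(s, priors.sd_df, scale)

    def sigma_logprior(ls0, ls1, zr):
        s0, s1, rho = math.exp(ls0), math.exp(ls1), math.tanh(zr)
        return (
            sd_lp(s0, group_sd_scale) + ls0
            + sd_lp(s1, group_sd_scale) + ls1
            + math.log1p(-(rho**2))  # uniform rho through tanh
        )

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(schedule.chains)

    mean_eggs = np.ones(n_morph)
    for m in range(n_morph):
        sel = yk[morph_idx == m]
        if sel.size:
            mean_eggs[m] = max(sel.mean(), 0.5)

    out = {
        "alpha": np.empty((schedule.chains, schedule.draws, n_morph)),
        "beta": np.empty((schedule.chains, schedule.draws, n_morph)),
        "sigma2_u0": np.empty((schedule.chains, schedule.draws)),
        "cov_u01": np.empty((schedule.chains, schedule.draws)),
        "sigma2_u1": np.empty((schedule.chains, schedule.draws)),
        "sigma2_eps": np.empty((schedule.chains, schedule.draws)),
    }

    for ci, cs in enumerate(chain_seeds):
        rng = np.random.default_rng(cs)
        alpha = np.log(mean_eggs) + rng.normal(0, 0.2, n_morph)
        beta = rng.normal(-0.03, 0.02, n_morph)
        u = np.zeros(n_group)
        v = np.zeros(n_group)
        eps = np.zeros(n)
        ls0 = math.log(0.2) + rng.normal(0, 0.2)
        ls1 = math.log(0.05) + rng.normal(0, 0.2)
        zr = 0.0
        lse = math.log(0.6) + rng.normal(0, 0.2)

        st_alpha = _StepSize(n_morph, 0.05)
        st_beta = _StepSize(n_morph, 0.02)
        st_u = _StepSize(n_group, 0.1)
        st_v = _StepSize(n_group, 0.03)
        st_eps = _StepSize(n, 0.2)
        st_sig = _StepSize((), 0.2, target=0.25)
        st_sig_nc = _StepSize((), 0.1, target=0.25)
        st_se = _StepSize((), 0.05)
        st_se_nc = _StepSize((), 0.05)
        st_tau = _StepSize((), 0.05)
        st_tbv = _StepSize((), 0.01)
        st_tae = _StepSize(n_morph, 0.05)
        st_tbe = _StepSize(n_morph, 0.01)
        st_tve = _StepSize(n_group, 0.01)
        st_tue = _StepSize(n_group, 0.05)
        steps = [st_alpha, st_beta, st_u, st_v, st_eps, st_sig, st_sig_nc,
                 st_se, st_se_nc, st_tau, st_tbv, st_tae, st_tbe, st_tve, st_tue]

        def mu_of(alpha, beta, u, v, eps):
            return alpha[morph_idx] + (beta[morph_idx] + v[group_idx]) * x + u[group_idx] + eps

        kept = 0
        for it in range(schedule.iterations):
            if it == schedule.burn_in:
                for s in steps:
                    s.frozen = True
            s0, s1, rho = math.exp(ls0), math.exp(ls1), math.tanh(zr)
            se = math.exp(lse)

            mu = mu_of(alpha, beta, u, v, eps)
            ll = pois_ll(mu)

            # morph intercepts
            da = st_alpha.s * rng.standard_normal(n_morph)
            ll_new = pois_ll(mu + da[morph_idx])
            logr = (
                np.bincount(morph_idx, ll_new, n_morph)
                - np.bincount(morph_idx, ll, n_morph)
                - ((alpha + da) ** 2 - alpha**2) / (2 * fe_var)
            )
            acc = _accept(rng, logr)
            st_alpha.update(acc)
            if acc.any():
                alpha = alpha + da * acc
                mu = mu + (da * acc)[morph_idx]
                ll = np.where(acc[morph_idx], ll_new, ll)

            # morph slopes
            db = st_beta.s * rng.standard_normal(n_morph)
            ll_new = pois_ll(mu + db[morph_idx] * x)
            logr = (
                np.bincount(morph_idx, ll_new, n_morph)
                - np.bincount(morph_idx, ll, n_morph)
                - ((beta + db) ** 2 - beta**2) / (2 * fe_var)
            )
            acc = _accept(rng, logr)
            st_beta.update(acc)
            if acc.any():
                beta = beta + db * acc
                mu = mu + (db * acc)[morph_idx] * x
                ll = np.where(acc[morph_idx], ll_new, ll)

            # group intercept deviations
            du = st_u.s * rng.standard_normal(n_group)
            ll_new = pois_ll(mu + du[group_idx])
            logr = (
                np.bincount(group_idx, ll_new, n_group)
                - np.bincount(group_idx, ll, n_group)
                + _bvn_ll(u + du, v, s0, s1, rho)
                - _bvn_ll(u, v, s0, s1, rho)
            )
            acc = _accept(rng, logr)
            st_u.update(acc)
            if acc.any():
                u = u + du * acc
                mu = mu + (du * acc)[group_idx]
                ll = np.where(acc[group_idx], ll_new, ll)

            # group slope deviations
            dv = st_v.s * rng.standard_normal(n_group)
            ll_new = pois_ll(mu + dv[group_idx] * x)
            logr = (
                np.bincount(group_idx, ll_new, n_group)
                - np.bincount(group_idx, ll, n_group)
                + _bvn_ll(u, v + dv, s0, s1, rho)
                - _bvn_ll(u, v, s0, s1, rho)
            )
            acc = _accept(rng, logr)
            st_v.update(acc)
            if acc.any():
                v = v + dv * acc
                mu = mu + (dv * acc)[group_idx] * x
                ll = np.where(acc[group_idx], ll_new, ll)

            # unit over-dispersion effects
            de = st_eps.s * rng.standard_normal(n)
            ll_new = pois_ll(mu + de)
            logr = ll_new - ll - ((eps + de) ** 2 - eps**2) / (2 * se**2)
            acc = _accept(rng, logr)
            st_eps.update(acc)
            if acc.any():
                eps = np.where(acc, eps + de, eps)
                mu = np.where(acc, mu + de, mu)

            # translations along confounded directions (likelihood
            # invariant, only priors change):
            # intercept level vs group intercepts
            d = st_tau.s * rng.standard_normal()
            logr = (
                -(((alpha + d) ** 2 - alpha**2).sum()) / (2 * fe_var)
                + _bvn_ll(u - d, v, s0, s1, rho).sum()
                - _bvn_ll(u, v, s0, s1, rho).sum()
            )
            acc = _accept(rng, logr)
            st_tau.update(acc)
            if acc:
                alpha = alpha + d
                u = u - d
            # slope level vs group slopes
            d = st_tbv.s * rng.standard_normal()
            logr = (
                -(((beta + d) ** 2 - beta**2).sum()) / (2 * fe_var)
                + _bvn_ll(u, v - d, s0, s1, rho).sum()
                - _bvn_ll(u, v, s0, s1, rho).sum()
            )
            acc = _accept(rng, logr)
            st_tbv.update(acc)
            if acc:
                beta = beta + d
                v = v - d
            # per-morph intercept vs unit effects
            dm = st_tae.s * rng.standard_normal(n_morph)
            de = dm[morph_idx]
            dprior = ((eps - de) ** 2 - eps**2) / (2 * se**2)
            logr = (
                -((alpha + dm) ** 2 - alpha**2) / (2 * fe_var)
                - np.bincount(morph_idx, dprior, n_morph)
            )
            acc = _accept(rng, logr)
            st_tae.update(acc)
            if acc.any():
                alpha = alpha + dm * acc
                eps = eps - de * acc[morph_idx]
            # per-morph slope vs unit effects along the mite-load direction
            dm = st_tbe.s * rng.standard_normal(n_morph)
            de = dm[morph_idx] * x
            dprior = ((eps - de) ** 2 - eps**2) / (2 * se**2)
            logr = (
                -((beta + dm) ** 2 - beta**2) / (2 * fe_var)
                - np.bincount(morph_idx, dprior, n_morph)
            )
            acc = _accept(rng, logr)
            st_tbe.update(acc)
            if acc.any():
                beta = beta + dm * acc
                eps = eps - de * acc[morph_idx]
            # per-group slope deviation vs unit effects along mites
            dg = st_tve.s * rng.standard_normal(n_group)
            de = dg[group_idx] * x
            dprior = ((eps - de) ** 2 - eps**2) / (2 * se**2)
            logr = (
                _bvn_ll(u, v + dg, s0, s1, rho)
                - _bvn_ll(u, v, s0, s1, rho)
                - np.bincount(group_idx, dprior, n_group)
            )
            acc = _accept(rng, logr)
            st_tve.update(acc)
            if acc.any():
                v = v + dg * acc
                eps = eps - de * acc[group_idx]
            # per-group intercept deviation vs unit effects
            dg = st_tue.s * rng.standard_normal(n_group)
            de = dg[group_idx]
            dprior = ((eps - de) ** 2 - eps**2) / (2 * se**2)
            logr = (
                _bvn_ll(u + dg, v, s0, s1, rho)
                - _bvn_ll(u, v, s0, s1, rho)
                - np.bincount(group_idx, dprior, n_group)
            )
            acc = _accept(rng, logr)
            st_tue.update(acc)
            if acc.any():
                u = u + dg * acc
                eps = eps - de * acc[group_idx]

            # 2x2 covariance, centred sweep
            th = np.array([ls0, ls1, zr])
            thp = th + st_sig.s * rng.standard_normal(3)
            s0p, s1p, rhop = math.exp(thp[0]), math.exp(thp[1]), math.tanh(thp[2])
            logr = (
                _bvn_ll(u, v, s0p, s1p, rhop).sum()
                - _bvn_ll(u, v, s0, s1, rho).sum()
                + sigma_logprior(*thp) - sigma_logprior(ls0, ls1, zr)
            )
            acc = _accept(rng, logr)
            st_sig.update(acc)
            if acc:
                ls0, ls1, zr = thp
                s0, s1, rho = s0p, s1p, rhop

            # 2x2 covariance, non-centred sweep (standardised effects fixed)
            L = np.array([[s0, 0.0], [rho * s1, s1 * math.sqrt(1 - rho**2)]])
            raw = np.linalg.solve(L, np.vstack([u, v]))
            th = np.array([ls0, ls1, zr])
            thp = th + st_sig_nc.s * rng.standard_normal(3)
            s0p, s1p, rhop = math.exp(thp[0]), math.exp(thp[1]), math.tanh(thp[2])
            Lp = np.array([[s0p, 0.0], [rhop * s1p, s1p * math.sqrt(1 - rhop**2)]])
            uvp = Lp @ raw
            mu_new = mu_of(alpha, beta, uvp[0], uvp[1], eps)
            logr = (
                pois_ll(mu_new).sum() - pois_ll(mu).sum()
                + sigma_logprior(*thp) - sigma_logprior(ls0, ls1, zr)
            )
            acc = _accept(rng, logr)
            st_sig_nc.update(acc)
            if acc:
                ls0, ls1, zr = thp
                s0, s1, rho = s0p, s1p, rhop
                u, v = uvp[0].copy(), uvp[1].copy()
                mu = mu_new

            # residual sd (interweaving)
            se = math.exp(lse)
            lsp = lse + st_se.s * rng.standard_normal()
            sp = math.exp(lsp)
            logr = (
                -n * (lsp - lse)
                - (eps**2).sum() / 2 * (1 / sp**2 - 1 / se**2)
                + sd_lp(sp, priors.sd_scale) - sd_lp(se, priors.sd_scale)
                + (lsp - lse)
            )
            acc = _accept(rng, logr)
            st_se.update(acc)
            if acc:
                lse = lsp
            se = math.exp(lse)
            eps_std = eps / se
            lsp = lse + st_se_nc.s * rng.standard_normal()
            sp = math.exp(lsp)
            mu_cur = mu_of(alpha, beta, u, v, eps)
            mu_new = mu_of(alpha, beta, u, v, sp * eps_std)
            logr = (
                pois_ll(mu_new).sum() - pois_ll(mu_cur).sum()
                + sd_lp(sp, priors.sd_scale) - sd_lp(se, priors.sd_scale)
                + (lsp - lse)
            )
            acc = _accept(rng, logr)
            st_se_nc.update(acc)
            if acc:
                lse = lsp
                eps = sp * eps_std

            post = it - schedule.burn_in
            if post >= 0 and (post + 1) % schedule.thin == 0 and kept < schedule.draws:
                s0, s1, rho = math.exp(ls0), math.exp(ls1), math.tanh(zr)
                out["alpha"][ci, kept] = alpha
                out["beta"][ci, kept] = beta
                out["sigma2_u0"][ci, kept] = s0**2
                out["cov_u01"][ci, kept] = rho * s0 * s1
                out["sigma2_u1"][ci, kept] = s1**2
                out["sigma2_eps"][ci, kept] = math.exp(2 * lse)
                kept += 1

    return out
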