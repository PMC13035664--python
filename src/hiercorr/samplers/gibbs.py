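"""Posterior samplers for the manifest, hierarchical, and contrast models.

Inverse-Wishart and scaled-inverse-Wishart priors admit fully conjugate
Gibbs cycles; the LKJ prior is handled by Metropolis-within-Gibbs with
adaptive random-walk updates on an unconstrained partial-correlation
parameterization of the correlation matrix and on log standard deviations.

Model layers (hierarchical case):

    Y_ijl | theta_ij ~ N(theta_ij, tau_j^2)
    theta_i ~ N_J(mu, Sigma),     Sigma = D(sigma) rho D(sigma)

with diffuse conjugate hyperpriors mu_j ~ N(0, (100 u)^2) and
tau_j^2 ~ Inverse-Gamma(.01, .01 u^2), where u is the pooled SD of the raw
scores (scale-aware but effectively flat). The contrast model adds per-cell
intercepts alpha_ij ~ N(0, (100 u)^2) and condition codes x_k = -.5, +.5,
so the multivariate layer applies to the within-task condition effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ..priors import (
    IWSpec,
    LKJSpec,
    SIWSpec,
    corr_from_cov,
    cov_from_corr,
    invwishart_bartlett,
    partial_from_corr,
    scale_logpdf,
)
from ..synthetic import ManifestDataset, TrialDataset
from .config import ChainConfig
from .results import FitResult, PosteriorDraws

__all__ = ["fit_manifest", "fit_hier", "fit_hier_iw", "fit_hier_siw",
           "fit_hier_lkj", "fit_contrast"]

_MU_SD_MULT = 100.0   # mu_j ~ N(0, (100 u)^2)
_TAU_A = 0.01         # tau_j^2 ~ IG(.01, .01 u^2)
_TAU_B = 0.01
_JITTER = 1e-6


def _invgamma(rng, shape, rate):
    # tiny shapes (diffuse priors in prior-only runs) can underflow the
    # gamma draw to 0; clamp to keep the reciprocal finite
    g = np.maximum(rng.gamma(shape, 1.0, size=np.shape(rate)), 1e-290)
    return rate / g


# ---------------------------------------------------------------------------
# Sufficient statistics
# ---------------------------------------------------------------------------

@dataclass
class _CellStats:
    """Per-cell summaries driving every full conditional."""

    design: str              # "hier" or "contrast"
    I: int
    J: int
    counts: np.ndarray       # (I, J) trials per cell (contrast: per condition)
    est: np.ndarray          # (I, J) cell means (hier) or condition contrasts
    c_theta: np.ndarray      # (I, J) precision multiplier: prec = c_theta/tau^2
    pooled_sd: float
    # tau residual ingredients
    ysum: np.ndarray         # hier: (I, J); contrast: (I, J, 2)
    ysq: np.ndarray          # same shape as ysum
    msum: np.ndarray | None = None  # contrast: (I, J) mean over conditions

    @property
    def balanced(self) -> bool:
        return bool(np.all(self.counts == self.counts.flat[0]))

    def n_obs_per_task(self) -> np.ndarray:
        if self.design == "contrast":
            return self.counts.sum(axis=0) * 2.0
        return self.counts.sum(axis=0)

    def sse(self, theta: np.ndarray, alpha: np.ndarray | None) -> np.ndarray:
        """Residual sum of squares per task at current theta (and alpha)."""
        if self.design == "hier":
            return (self.ysq - 2.0 * theta * self.ysum
                    + self.counts * theta ** 2).sum(axis=0)
        c1 = alpha - 0.5 * theta
        c2 = alpha + 0.5 * theta
        out = np.zeros(self.J)
        for k, c in enumerate((c1, c2)):
            out += (self.ysq[:, :, k] - 2.0 * c * self.ysum[:, :, k]
                    + self.counts * c ** 2).sum(axis=0)
        return out

    def within_cell_sd(self) -> np.ndarray:
        """Pooled within-cell SD per task (initialization for tau)."""
        if self.design == "hier":
            n = self.counts
            var = (self.ysq - self.ysum ** 2 / n) / np.maximum(n - 1, 1)
            return np.sqrt(np.maximum(var.mean(axis=0), 1e-12))
        n = self.counts[:, :, None]
        var = (self.ysq - self.ysum ** 2 / n) / np.maximum(n - 1, 1)
        return np.sqrt(np.maximum(var.mean(axis=(0, 2)), 1e-12))


def _stats_from_trials(data: TrialDataset) -> _CellStats:
    data.validate_dense()
    tab = data.table
    I, J = data.n_individuals, data.n_tasks
    if data.has_conditions:
        conds = sorted(tab["condition"].dropna().unique())
        if len(conds) != 2:
            raise ValueError(f"contrast designs need exactly 2 conditions, "
                             f"got {len(conds)}")
        g = tab.groupby(["individual", "task", "condition"], observed=True)["score"]
        n = g.size().to_numpy().reshape(I, J, 2).astype(float)
        s = g.sum().to_numpy().reshape(I, J, 2)
        qq = g.agg(lambda v: float(np.sum(v.to_numpy() ** 2))).to_numpy().reshape(I, J, 2)
        if not np.all(n == n.flat[0]):
            raise ValueError("contrast designs must be balanced per cell")
        m = s / n
        est = m[:, :, 1] - m[:, :, 0]          # x = +.5 minus x = -.5
        msum = 0.5 * (m[:, :, 0] + m[:, :, 1])
        counts = n[:, :, 0]
        return _CellStats(design="contrast", I=I, J=J, counts=counts, est=est,
                          c_theta=counts / 2.0,
                          pooled_sd=float(tab["score"].std()),
                          ysum=s, ysq=qq, msum=msum)
    g = tab.groupby(["individual", "task"], observed=True)["score"]
    n = g.size().to_numpy().reshape(I, J).astype(float)
    if (n < 2).any():
        raise ValueError("hierarchical fits need L >= 2 trials per cell")
    s = g.sum().to_numpy().reshape(I, J)
    qq = g.agg(lambda v: float(np.sum(v.to_numpy() ** 2))).to_numpy().reshape(I, J)
    return _CellStats(design="hier", I=I, J=J, counts=n, est=s / n,
                      c_theta=n, pooled_sd=float(tab["score"].std()),
                      ysum=s, ysq=qq)


# ---------------------------------------------------------------------------
# Sigma updates per prior family
# ---------------------------------------------------------------------------

class _IWSigma:
    name = "iw"

    def __init__(self, spec: IWSpec, J: int, cfg: ChainConfig, rng):
        if spec.J != J:
            raise ValueError(f"prior is {spec.J}-dimensional, data {J}")
        self.spec = spec

    def step(self, rng, scatter, n_obs):
        Sigma = invwishart_bartlett(rng, self.spec.v + n_obs,
                                    self.spec.S + scatter)
        sd, rho = corr_from_cov(Sigma)
        return Sigma, sd, rho

    def finalize(self):
        return {}, []


class _SIWSigma:
    name = "siw"

    def __init__(self, spec: SIWSpec, J: int, cfg: ChainConfig, rng):
        if spec.J != J:
            raise ValueError(f"prior is {spec.J}-dimensional, data {J}")
        self.spec = spec
        self.alpha = spec.s ** 2  # mixing scales, started at nominal

    def step(self, rng, scatter, n_obs):
        v, J = self.spec.v, self.spec.J
        Psi = 2.0 * v * np.diag(1.0 / self.alpha) + scatter
        Sigma = invwishart_bartlett(rng, v + J - 1 + n_obs, Psi)
        # alpha_j | Sigma ~ IG((v + J)/2, v (Sigma^{-1})_jj + 1/s_j^2)
        prec_diag = np.diag(np.linalg.inv(Sigma))
        rate = v * prec_diag + 1.0 / self.spec.s ** 2
        self.alpha = _invgamma(rng, 0.5 * (v + J), rate)
        sd, rho = corr_from_cov(Sigma)
        return Sigma, sd, rho

    def finalize(self):
        return {}, []


def _corr_from_partial_single(P: np.ndarray) -> np.ndarray:
    """Scalar-loop vine reconstruction; faster than the array version for
    one matrix inside the Metropolis loop."""
    J = P.shape[0]
    Pl = P.tolist()
    R = [[0.0] * J for _ in range(J)]
    for a in range(J):
        R[a][a] = 1.0
    for i in range(J - 1):
        for j in range(i + 1, J):
            p = Pl[i][j]
            for k in range(i - 1, -1, -1):
                p = (p * math.sqrt((1 - Pl[k][i] ** 2) * (1 - Pl[k][j] ** 2))
                     + Pl[k][i] * Pl[k][j])
            R[i][j] = R[j][i] = p
    return np.asarray(R)


def _rho_factor(rho):
    """(inverse, log determinant) of a correlation matrix; LinAlgError if
    not positive definite."""
    L = np.linalg.cholesky(rho)
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    return np.linalg.inv(rho), logdet


class _AdaptiveStep:
    """Robbins-Monro step-size adaptation toward a target acceptance rate."""

    def __init__(self, init_step, target):
        self.log_step = math.log(init_step)
        self.target = target
        self.t = 0
        self.accepted = 0
        self.proposed = 0

    @property
    def step(self):
        return math.exp(self.log_step)

    def update(self, accepted: bool, adapting: bool):
        self.proposed += 1
        self.accepted += accepted
        if adapting:
            self.t += 1
            gamma = (self.t + 10.0) ** -0.6
            self.log_step += gamma * ((1.0 if accepted else 0.0) - self.target)

    @property
    def rate(self):
        return self.accepted / max(self.proposed, 1)


class _LKJSigma:
    """Metropolis block for (rho, sigma) under LKJ(eta) x scale priors.

    rho is parameterized by unconstrained y with z = tanh(y) the canonical
    partial correlations; their LKJ-implied prior is an independent product
    of scaled Betas, so the Metropolis target needs only the tanh Jacobian.
    sigma is updated on the log scale.
    """

    name = "lkj"

    def __init__(self, spec: LKJSpec, J: int, cfg: ChainConfig, rng):
        if spec.J != J:
            raise ValueError(f"prior is {spec.J}-dimensional, data {J}")
        self.spec = spec
        self.J = J
        self.cfg = cfg
        self.pairs = [(i, j) for i in range(J) for j in range(i + 1, J)]
        # Beta(b, b) exponent per pair: prior density (1 - z^2)^(b - 1),
        # b = eta + (J - 2 - i)/2 for vine row i; +1 from the tanh Jacobian.
        self.zexp = np.array([spec.eta + (J - 2 - i) / 2.0
                              for i, _ in self.pairs])
        self.y = np.zeros(len(self.pairs))
        self.sigma = spec.s.astype(float).copy()
        self.rho = np.eye(J)
        self.steps_y = [_AdaptiveStep(cfg.init_step, cfg.target_accept)
                        for _ in self.pairs]
        self.steps_s = [_AdaptiveStep(cfg.init_step, cfg.target_accept)
                        for _ in range(J)]
        self.adapting = True
        self._refresh()

    def init_state(self, sd, rho):
        self.sigma = np.maximum(np.asarray(sd, dtype=float), 1e-8)
        P = partial_from_corr(rho)
        z = np.array([np.clip(P[i, j], -0.999, 0.999) for i, j in self.pairs])
        self.y = np.arctanh(z)
        self._refresh()

    def _rho_from_y(self, y):
        P = np.zeros((self.J, self.J))
        z = np.tanh(y)
        for (i, j), zv in zip(self.pairs, z):
            P[i, j] = zv
        return _corr_from_partial_single(P), z

    def _refresh(self):
        self.rho, self.z = self._rho_from_y(self.y)
        self.rho_inv, self.logdet = _rho_factor(self.rho)

    def _z_logprior(self, z):
        return float(np.sum(self.zexp * np.log1p(-(z ** 2))))

    def _sigma_logprior(self, sigma):
        return float(np.sum(scale_logpdf(self.spec.scale_family,
                                         self.spec.s, sigma)))

    def _ll(self, rho_inv, logdet, M, log_sd_sum, n_obs):
        """MVN log likelihood given M = scatter scaled by 1/(sd_j sd_k)."""
        if n_obs == 0:
            return 0.0
        return (-n_obs * log_sd_sum - 0.5 * n_obs * logdet
                - 0.5 * float(np.sum(rho_inv * M)))

    def step(self, rng, scatter, n_obs):
        M = scatter / np.outer(self.sigma, self.sigma)
        log_sd_sum = float(np.log(self.sigma).sum())
        cur_ll = self._ll(self.rho_inv, self.logdet, M, log_sd_sum, n_obs)
        cur_zp = self._z_logprior(self.z)
        cur_sp = self._sigma_logprior(self.sigma)
        for _ in range(self.cfg.n_scans):
            # correlation components
            for c, ad in enumerate(self.steps_y):
                prop = self.y.copy()
                prop[c] += ad.step * rng.standard_normal()
                rho_p, z_p = self._rho_from_y(prop)
                try:
                    inv_p, logdet_p = _rho_factor(rho_p)
                except np.linalg.LinAlgError:
                    ad.update(False, self.adapting)
                    continue
                ll_p = self._ll(inv_p, logdet_p, M, log_sd_sum, n_obs)
                zp_p = self._z_logprior(z_p)
                if math.log(rng.uniform()) < (ll_p + zp_p) - (cur_ll + cur_zp):
                    self.y, self.z, self.rho = prop, z_p, rho_p
                    self.rho_inv, self.logdet = inv_p, logdet_p
                    cur_ll, cur_zp = ll_p, zp_p
                    ad.update(True, self.adapting)
                else:
                    ad.update(False, self.adapting)
            # scale components (log-scale random walk)
            for j, ad in enumerate(self.steps_s):
                prop = self.sigma.copy()
                prop[j] *= math.exp(ad.step * rng.standard_normal())
                M_p = scatter / np.outer(prop, prop)
                ls_p = float(np.log(prop).sum())
                ll_p = self._ll(self.rho_inv, self.logdet, M_p, ls_p, n_obs)
                sp_p = self._sigma_logprior(prop) + math.log(prop[j])
                cur_j = cur_sp + math.log(self.sigma[j])
                # both sides carry the log-scale Jacobian of their own state
                if math.log(rng.uniform()) < (ll_p + sp_p) - (cur_ll + cur_j):
                    self.sigma = prop
                    M, log_sd_sum = M_p, ls_p
                    cur_ll = ll_p
                    cur_sp = self._sigma_logprior(prop)
                    ad.update(True, self.adapting)
                else:
                    ad.update(False, self.adapting)
        Sigma = cov_from_corr(self.sigma, self.rho)
        return Sigma, self.sigma.copy(), self.rho.copy()

    def finalize(self):
        acc = {f"y[{i + 1},{j + 1}]": ad.rate
               for (i, j), ad in zip(self.pairs, self.steps_y)}
        acc.update({f"sigma[{j + 1}]": ad.rate
                    for j, ad in enumerate(self.steps_s)})
        warns = []
        low = [k for k, v in acc.items() if v < 0.05]
        if low:
            warns.append(f"acceptance below .05 after adaptation: {low}")
        return acc, warns


def _make_sigma_update(prior, J, cfg, rng):
    if isinstance(prior, IWSpec):
        return _IWSigma(prior, J, cfg, rng)
    if isinstance(prior, SIWSpec):
        return _SIWSigma(prior, J, cfg, rng)
    if isinstance(prior, LKJSpec):
        return _LKJSigma(prior, J, cfg, rng)
    raise TypeError(f"unsupported prior spec {type(prior).__name__}")


# ---------------------------------------------------------------------------
# Chain runners
# ---------------------------------------------------------------------------

def _draw_mu(rng, theta_sum, n_obs, Sigma_inv, prior_prec):
    """Conjugate normal update for mu given true scores (or observations)."""
    J = theta_sum.size
    prec = prior_prec * np.eye(J) + n_obs * Sigma_inv
    V = np.linalg.inv(prec)
    mean = V @ (Sigma_inv @ theta_sum)
    C = np.linalg.cholesky(V)
    return mean + C @ rng.standard_normal(J)


def _init_sigma(est: np.ndarray) -> np.ndarray:
    S0 = np.cov(est, rowvar=False)
    S0 = np.atleast_2d(S0) + _JITTER * np.eye(est.shape[1])
    # guard against degenerate cell-mean covariance
    w, V = np.linalg.eigh(S0)
    w = np.clip(w, 1e-10 * max(w.max(), 1.0), None)
    return (V * w) @ V.T


def _run_hier_chain(stats: _CellStats, prior, cfg: ChainConfig, rng,
                    store_theta: bool):
    I, J = stats.I, stats.J
    prior_only = cfg.prior_only
    u = 1.0 if prior_only else max(stats.pooled_sd, 1e-12)
    mu_prec = 1.0 / (_MU_SD_MULT * u) ** 2
    tau_b = _TAU_B * u ** 2

    upd = _make_sigma_update(prior, J, cfg, rng)

    # initialization at data-driven values
    if prior_only:
        theta = np.zeros((0, J))
        alpha = None
        mu = np.zeros(J)
        tau2 = np.ones(J)
        Sigma = np.eye(J)
    else:
        theta = stats.est.copy()
        alpha = stats.msum.copy() if stats.design == "contrast" else None
        mu = stats.est.mean(axis=0)
        tau2 = stats.within_cell_sd() ** 2
        Sigma = _init_sigma(stats.est)
        if isinstance(upd, _LKJSigma):
            sd0, rho0 = corr_from_cov(Sigma)
            upd.init_state(sd0, rho0)

    n_iter = cfg.n_burn + cfg.n_keep
    keep_mu = np.empty((cfg.n_keep, J))
    keep_sd = np.empty((cfg.n_keep, J))
    keep_tau = np.empty((cfg.n_keep, J))
    npairs = J * (J - 1) // 2
    keep_rho = np.empty((cfg.n_keep, npairs))
    keep_theta = (np.empty((cfg.n_keep, I, J)) if store_theta and not prior_only
                  else None)
    iu = np.triu_indices(J, 1)
    balanced = stats.balanced

    for it in range(n_iter):
        if isinstance(upd, _LKJSigma):
            upd.adapting = it < cfg.n_burn
        if not prior_only:
            Sigma_inv = np.linalg.inv(Sigma)
            # theta | .
            w = stats.c_theta / tau2  # (I, J)
            base = Sigma_inv @ mu
            if balanced:
                prec = Sigma_inv + np.diag(w[0])
                V = np.linalg.inv(prec)
                CV = np.linalg.cholesky(V)
                means = (w * stats.est + base) @ V
                theta = means + rng.standard_normal((I, J)) @ CV.T
            else:
                theta = np.empty((I, J))
                noise = rng.standard_normal((I, J))
                for i in range(I):
                    prec = Sigma_inv + np.diag(w[i])
                    V = np.linalg.inv(prec)
                    CV = np.linalg.cholesky(V)
                    theta[i] = V @ (w[i] * stats.est[i] + base) + CV @ noise[i]
            # alpha | . (contrast only; orthogonal to theta under +-.5 codes)
            if stats.design == "contrast":
                prec_a = 2.0 * stats.counts / tau2 + mu_prec
                mean_a = (2.0 * stats.counts / tau2) * stats.msum / prec_a
                alpha = mean_a + rng.standard_normal((I, J)) / np.sqrt(prec_a)
            # mu | .
            mu = _draw_mu(rng, theta.sum(axis=0), I, Sigma_inv, mu_prec)
            # tau^2 | .
            sse = stats.sse(theta, alpha)
            tau2 = _invgamma(rng, _TAU_A + 0.5 * stats.n_obs_per_task(),
                             tau_b + 0.5 * sse)
            centered = theta - mu
            scatter = centered.T @ centered
            Sigma, sd, rho = upd.step(rng, scatter, I)
        else:
            tau2 = _invgamma(rng, np.full(J, _TAU_A), np.full(J, tau_b))
            Sigma, sd, rho = upd.step(rng, np.zeros((J, J)), 0)
            mu = rng.standard_normal(J) / math.sqrt(mu_prec)

        k = it - cfg.n_burn
        if k >= 0:
            keep_mu[k] = mu
            keep_sd[k] = sd
            keep_tau[k] = np.sqrt(tau2)
            keep_rho[k] = rho[iu]
            if keep_theta is not None:
                keep_theta[k] = theta
    acc, warns = upd.finalize()
    return dict(mu=keep_mu, sigma=keep_sd, tau=keep_tau, rho=keep_rho,
                theta=keep_theta, acceptance=acc, warnings=warns)


def _run_manifest_chain(Y: np.ndarray, prior, cfg: ChainConfig, rng,
                        mu_fixed):
    I, J = Y.shape
    prior_only = cfg.prior_only or I == 0
    u = 1.0 if prior_only else max(float(Y.std()), 1e-12)
    mu_prec = 1.0 / (_MU_SD_MULT * u) ** 2

    upd = _make_sigma_update(prior, J, cfg, rng)
    if prior_only:
        mu = np.zeros(J) if mu_fixed is None else np.asarray(mu_fixed, float)
    else:
        mu = Y.mean(axis=0) if mu_fixed is None else np.asarray(mu_fixed, float)
        if isinstance(upd, _LKJSigma):
            sd0, rho0 = corr_from_cov(_init_sigma(Y))
            upd.init_state(sd0, rho0)
    Sigma = np.eye(J)

    keep_mu = np.empty((cfg.n_keep, J))
    keep_sd = np.empty((cfg.n_keep, J))
    npairs = J * (J - 1) // 2
    keep_rho = np.empty((cfg.n_keep, npairs))
    iu = np.triu_indices(J, 1)

    for it in range(cfg.n_burn + cfg.n_keep):
        if isinstance(upd, _LKJSigma):
            upd.adapting = it < cfg.n_burn
        if prior_only:
            Sigma, sd, rho = upd.step(rng, np.zeros((J, J)), 0)
            if mu_fixed is None:
                mu = rng.standard_normal(J) / math.sqrt(mu_prec)
        else:
            centered = Y - mu
            Sigma, sd, rho = upd.step(rng, centered.T @ centered, I)
            if mu_fixed is None:
                mu = _draw_mu(rng, Y.sum(axis=0), I,
                              np.linalg.inv(Sigma), mu_prec)
        k = it - cfg.n_burn
        if k >= 0:
            keep_mu[k] = mu
            keep_sd[k] = sd
            keep_rho[k] = rho[iu]
    acc, warns = upd.finalize()
    return dict(mu=keep_mu, sigma=keep_sd,
                tau=np.zeros((cfg.n_keep, J)), rho=keep_rho,
                theta=None, acceptance=acc, warnings=warns)


def _assemble(chains: list[dict], model: str, cfg: ChainConfig) -> FitResult:
    stack = lambda key: np.stack([c[key] for c in chains])
    theta = None
    if chains[0]["theta"] is not None:
        theta = stack("theta")
    draws = PosteriorDraws(mu=stack("mu"), sigma=stack("sigma"),
                           tau=stack("tau"), rho=stack("rho"),
                           model=model, theta=theta)
    acc = {}
    warns = []
    for c, ch in enumerate(chains):
        for k, v in ch["acceptance"].items():
            acc[f"chain{c + 1}:{k}"] = v
        warns.extend(ch["warnings"])
    return FitResult.from_draws(draws, acceptance=acc, warnings_=warns)


def _chain_rngs(cfg: ChainConfig):
    ss = np.random.SeedSequence(cfg.seed)
    return [np.random.default_rng(child) for child in ss.spawn(cfg.n_chains)]


# ---------------------------------------------------------------------------
# Public fitting interface
# ---------------------------------------------------------------------------

def fit_manifest(data: ManifestDataset, prior, cfg: ChainConfig,
                 mu_fixed=None) -> FitResult:
    """Fit the manifest model Y_i ~ N_J(mu, Sigma) under any prior family.

    ``mu_fixed`` pins the mean vector (used by conjugacy oracles); I = 0 is
    allowed and reduces every update to its prior.
    """
    Y = np.asarray(data.scores, dtype=float)
    I, J = Y.shape
    if I > 0 and not cfg.prior_only:
        if I <= J:
            raise ValueError(f"need more individuals than tasks (I={I}, J={J})")
        if np.linalg.matrix_rank(Y - Y.mean(axis=0)) < J:
            raise ValueError("rank-deficient data: some task scores are "
                             "linearly dependent")
    chains = [_run_manifest_chain(Y, prior, cfg, rng, mu_fixed)
              for rng in _chain_rngs(cfg)]
    tag = f"manifest-{_make_sigma_update(prior, J, cfg, np.random.default_rng(0)).name}"
    return _assemble(chains, tag, cfg)


def _fit_hier_generic(data: TrialDataset, prior, cfg: ChainConfig,
                      expect_contrast: bool) -> FitResult:
    stats = _stats_from_trials(data)
    if expect_contrast and stats.design != "contrast":
        raise ValueError("fit_contrast requires a two-condition dataset")
    if not expect_contrast and stats.design == "contrast":
        raise ValueError("dataset has conditions; use fit_contrast")
    chains = [_run_hier_chain(stats, prior, cfg, rng, cfg.store_theta)
              for rng in _chain_rngs(cfg)]
    fam = _make_sigma_update(prior, stats.J, cfg, np.random.default_rng(0)).name
    tag = f"{'contrast' if expect_contrast else 'hier'}-{fam}"
    return _assemble(chains, tag, cfg)


def fit_hier_iw(data: TrialDataset, prior: IWSpec, cfg: ChainConfig) -> FitResult:
    """Conjugate Gibbs fit of the hierarchical model under an IW prior."""
    if not isinstance(prior, IWSpec):
        raise TypeError("fit_hier_iw expects an IWSpec")
    return _fit_hier_generic(data, prior, cfg, expect_contrast=False)


def fit_hier_siw(data: TrialDataset, prior: SIWSpec, cfg: ChainConfig) -> FitResult:
    """Gibbs fit under the scaled-inverse-Wishart mixture prior."""
    if not isinstance(prior, SIWSpec):
        raise TypeError("fit_hier_siw expects an SIWSpec")
    return _fit_hier_generic(data, prior, cfg, expect_contrast=False)


def fit_hier_lkj(data: TrialDataset, prior: LKJSpec, cfg: ChainConfig) -> FitResult:
    """Metropolis-within-Gibbs fit under the LKJ + scale-prior family."""
    if not isinstance(prior, LKJSpec):
        raise TypeError("fit_hier_lkj expects an LKJSpec")
    return _fit_hier_generic(data, prior, cfg, expect_contrast=False)


def fit_hier(data: TrialDataset, prior, cfg: ChainConfig) -> FitResult:
    """Dispatch on the prior family (hierarchical designs)."""
    return _fit_hier_generic(data, prior, cfg, expect_contrast=False)


def fit_contrast(data: TrialDataset, prior, cfg: ChainConfig) -> FitResult:
    """Fit the two-condition contrast model; correlations are over slopes."""
    return _fit_hier_generic(data, prior, cfg, expect_contrast=True)
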