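"""Priors on covariance and correlation matrices.

Three families are supported for the between-individual covariance matrix
Sigma (equivalently, for standard deviations sigma and correlation matrix
rho linked by Sigma = D(sigma) rho D(sigma)):

* **Inverse Wishart (IW)** — conjugate prior directly on Sigma with scale
  matrix S and degrees of freedom v. At the default v = J + 1 with diagonal
  S the marginal prior on each pairwise correlation is uniform on (-1, 1),
  but correlation and scale are dependent a priori.
* **Scaled inverse Wishart (SIW)** — a continuous mixture of inverse
  Wisharts over per-variable scales: Sigma | alpha ~ IW(v + J - 1,
  2 v D(1/alpha)), alpha_j ~ Inverse-Gamma(1/2, rate 1/s_j^2). The default
  v = 2 again gives uniform marginal correlations (for any J) and half-t(2,
  s_j) marginals on the standard deviations, with weaker scale/correlation
  dependence than the IW.
* **LKJ** — a distribution directly on correlation matrices with shape eta
  (uniform over all correlation matrices at eta = 1), paired with separate
  scale priors on the standard deviations (half-t with 2 df by default).
  Scale and correlation are independent by construction.

Sampling for the LKJ uses the vine construction: canonical partial
correlations at tree level k are independent 2 Beta(b_k, b_k) - 1 with
b_k = eta + (J - 1 - k) / 2, which implies the known marginal
(rho_12 + 1)/2 ~ Beta(eta + (J-2)/2, eta + (J-2)/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "IWSpec", "SIWSpec", "LKJSpec",
    "corr_from_cov", "cov_from_corr",
    "sample_iw", "sample_siw", "sample_lkj_corr", "sample_scale",
    "scale_logpdf", "corr_from_partial", "partial_from_corr",
    "lkj_marginal_beta_param", "prior_panels", "default_iw",
    "SCALE_FAMILIES",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IWSpec:
    """Inverse-Wishart prior: Sigma ~ IW(S, v), v > J - 1, S sym. PD."""

    v: float
    S: np.ndarray

    def __post_init__(self):
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        J = S.shape[0]
        if S.ndim != 2 or S.shape != (J, J):
            raise ValueError("S must be square")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("S must be symmetric")
        evals = np.linalg.eigvalsh(S)
        if evals.min() <= 0:
            raise ValueError("S must be positive definite")
        if self.v <= J - 1:
            raise ValueError(f"need v > J - 1 = {J - 1}, got v = {self.v}")

    @property
    def J(self) -> int:
        return self.S.shape[0]

    def to_dict(self):
        return {"family": "iw", "v": float(self.v), "S": self.S.tolist()}


def default_iw(J: int, s: float = 1.0) -> IWSpec:
    """Default IW: v = J + 1 (uniform marginal correlations), S = s^2 I.

    The diagonal entries of S are the expected variances, so ``s`` is on the
    standard-deviation scale.
    """
    return IWSpec(v=J + 1, S=(s ** 2) * np.eye(J))


@dataclass(frozen=True)
class SIWSpec:
    """Scaled inverse-Wishart prior with shape v (default 2) and SD scales s."""

    s: np.ndarray
    v: float = 2.0

    def __post_init__(self):
        s = np.atleast_1d(np.asarray(self.s, dtype=float))
        object.__setattr__(self, "s", s)
        if (s <= 0).any():
            raise ValueError("scales must be positive")
        if self.v <= 0:
            raise ValueError("need v > 0")

    @property
    def J(self) -> int:
        return self.s.size

    def to_dict(self):
        return {"family": "siw", "v": float(self.v), "s": self.s.tolist()}


SCALE_FAMILIES = ("half_t_2", "half_normal", "half_cauchy", "exponential",
                  "gamma", "lognormal", "uniform")


@dataclass(frozen=True)
class LKJSpec:
    """LKJ(eta) on the correlation matrix plus per-SD scale priors.

    ``scale_family`` names the prior on each sigma_j; all families are
    parameterized so their central mass sits near the nominal scale s_j
    (see ``sample_scale``).
    """

    s: np.ndarray
    eta: float = 1.0
    scale_family: str = "half_t_2"

    def __post_init__(self):
        s = np.atleast_1d(np.asarray(self.s, dtype=float))
        object.__setattr__(self, "s", s)
        if (s <= 0).any():
            raise ValueError("scales must be positive")
        if self.eta <= 0:
            raise ValueError("need eta > 0")
        if self.scale_family not in SCALE_FAMILIES:
            raise ValueError(
                f"unknown scale family {self.scale_family!r}; "
                f"supported: {', '.join(SCALE_FAMILIES)}"
            )

    @property
    def J(self) -> int:
        return self.s.size

    def to_dict(self):
        return {"family": "lkj", "eta": float(self.eta), "s": self.s.tolist(),
                "scale_family": self.scale_family}


def spec_to_yaml(spec) -> str:
    return yaml.safe_dump(spec.to_dict(), sort_keys=False)


def spec_from_dict(d: dict):
    d = dict(d)
    fam = d.pop("family")
    if fam == "iw":
        return IWSpec(v=d["v"], S=np.asarray(d["S"]))
    if fam == "siw":
        return SIWSpec(v=d["v"], s=np.asarray(d["s"]))
    if fam == "lkj":
        return LKJSpec(eta=d["eta"], s=np.asarray(d["s"]),
                       scale_family=d.get("scale_family", "half_t_2"))
    raise ValueError(f"unknown prior family {fam!r}")


def spec_from_yaml(text: str):
    return spec_from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Covariance <-> correlation
# ---------------------------------------------------------------------------

def corr_from_cov(Sigma: np.ndarray):
    """Split a covariance matrix into SDs and a correlation matrix.

    Supports a single JxJ matrix or a stack (..., J, J).
    """
    Sigma = np.asarray(Sigma, dtype=float)
    d = np.diagonal(Sigma, axis1=-2, axis2=-1)
    if (d <= 0).any():
        raise ValueError("covariance diagonal must be positive")
    sd = np.sqrt(d)
    rho = Sigma / (sd[..., :, None] * sd[..., None, :])
    return sd, rho


def cov_from_corr(sd: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Sigma = D(sd) rho D(sd)."""
    sd = np.asarray(sd, dtype=float)
    return rho * (sd[..., :, None] * sd[..., None, :])


# ---------------------------------------------------------------------------
# Partial-correlation (vine) parameterization
# ---------------------------------------------------------------------------

def corr_from_partial(P: np.ndarray) -> np.ndarray:
    """Map canonical partial correlations (C-vine) to a correlation matrix.

    ``P[..., i, j]`` (i < j, 0-based) is the partial correlation of
    variables i and j given variables 0..i-1; row 0 holds marginal
    correlations with variable 0.
    """
    P = np.asarray(P, dtype=float)
    J = P.shape[-1]
    R = np.zeros_like(P)
    R[..., range(J), range(J)] = 1.0
    for i in range(J - 1):
        for j in range(i + 1, J):
            p = P[..., i, j]
            for k in range(i - 1, -1, -1):
                p = (p * np.sqrt((1 - P[..., k, i] ** 2)
                                 * (1 - P[..., k, j] ** 2))
                     + P[..., k, i] * P[..., k, j])
            R[..., i, j] = p
            R[..., j, i] = p
    return R


def partial_from_corr(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`corr_from_partial` for a single correlation matrix."""
    R = np.asarray(R, dtype=float)
    J = R.shape[-1]
    P = np.zeros((J, J))
    Rk = R.copy()
    for k in range(J - 1):
        P[k, k + 1:] = Rk[k, k + 1:]
        nxt = np.eye(J)
        for i in range(k + 1, J):
            for j in range(i + 1, J):
                den = np.sqrt((1 - Rk[k, i] ** 2) * (1 - Rk[k, j] ** 2))
                nxt[i, j] = nxt[j, i] = (Rk[i, j] - Rk[k, i] * Rk[k, j]) / den
        Rk = nxt
    return P


def lkj_marginal_beta_param(eta: float, J: int) -> float:
    """Beta(a, a) parameter of the LKJ marginal: (rho+1)/2 ~ Beta(a, a)."""
    return eta + (J - 2) / 2.0


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_iw(spec: IWSpec, n_draws: int, seed) -> np.ndarray:
    """I.i.d. inverse-Wishart covariance draws, shape (n_draws, J, J)."""
    rng = _rng(seed)
    draws = np.asarray(stats.invwishart.rvs(df=spec.v, scale=spec.S,
                                            size=n_draws, random_state=rng))
    return draws.reshape(n_draws, spec.J, spec.J)


def invwishart_bartlett(rng: np.random.Generator, df: float,
                        scale: np.ndarray) -> np.ndarray:
    """One inverse-Wishart draw via the Bartlett decomposition.

    Draws W ~ Wishart(df, scale^{-1}) and returns W^{-1}; used in the Gibbs
    inner loops where scipy's distribution-object overhead matters.
    """
    J = scale.shape[0]
    # Bartlett factor of Wishart(df, I): lower triangular A
    A = np.zeros((J, J))
    idx = np.tril_indices(J, -1)
    A[idx] = rng.standard_normal(len(idx[0]))
    A[range(J), range(J)] = np.sqrt(rng.chisquare(df - np.arange(J)))
    # With C = chol(scale) and B = C^{-T} (so B B' = scale^{-1}):
    # W = B (A A') B' ~ Wishart(df, scale^{-1}), hence
    # Sigma = W^{-1} = C A^{-T} A^{-1} C' = M' M with M = A^{-1} C'.
    C = np.linalg.cholesky(scale)
    from scipy.linalg import solve_triangular
    M = solve_triangular(A, C.T, lower=True)
    return M.T @ M


def sample_siw(spec: SIWSpec, n_draws: int, seed) -> np.ndarray:
    """Scaled-inverse-Wishart draws via the exact two-stage mixture.

    alpha_j ~ Inverse-Gamma(1/2, rate 1/s_j^2), then
    Sigma | alpha ~ IW(v + J - 1, 2 v D(1/alpha)).
    """
    rng = _rng(seed)
    J = spec.J
    alpha = stats.invgamma.rvs(a=0.5, scale=1.0 / spec.s ** 2,
                               size=(n_draws, J), random_state=rng)
    df = spec.v + J - 1
    out = np.empty((n_draws, J, J))
    for i in range(n_draws):
        out[i] = invwishart_bartlett(rng, df, 2.0 * spec.v * np.diag(1.0 / alpha[i]))
    return out


def sample_siw_scipy(spec: SIWSpec, n_draws: int, seed) -> np.ndarray:
    """Independent route through scipy's inverse-Wishart sampler.

    Serves as a cross-check in tests that the two mechanizations of the
    mixture agree in distribution.
    """
    rng = _rng(seed)
    J = spec.J
    alpha = stats.invgamma.rvs(a=0.5, scale=1.0 / spec.s ** 2,
                               size=(n_draws, J), random_state=rng)
    df = spec.v + J - 1
    out = np.empty((n_draws, J, J))
    for i in range(n_draws):
        out[i] = stats.invwishart.rvs(df=df,
                                      scale=2.0 * spec.v * np.diag(1.0 / alpha[i]),
                                      random_state=rng)
    return out


def sample_lkj_corr(eta: float, J: int, n_draws: int, seed) -> np.ndarray:
    """LKJ(eta) correlation-matrix draws via the vine construction."""
    if J < 2:
        raise ValueError("need J >= 2")
    if eta <= 0:
        raise ValueError("need eta > 0")
    rng = _rng(seed)
    P = np.zeros((n_draws, J, J))
    for i in range(J - 1):
        b = eta + (J - 2 - i) / 2.0
        P[:, i, i + 1:] = 2.0 * rng.beta(b, b, size=(n_draws, J - 1 - i)) - 1.0
    return corr_from_partial(P)


def sample_lkj_rejection(eta: float, J: int, n_draws: int, seed,
                         max_tries: int = 2_000_000) -> np.ndarray:
    """Brute-force LKJ draws by accept/reject; oracle for small J.

    Proposes i.i.d. Uniform(-1,1) off-diagonals, accepts PD matrices with
    probability det(rho)^(eta-1) (eta >= 1). Exact but slow; test use only.
    """
    if eta < 1:
        raise ValueError("rejection oracle implemented for eta >= 1")
    rng = _rng(seed)
    out = np.empty((n_draws, J, J))
    got = 0
    npairs = J * (J - 1) // 2
    iu = np.triu_indices(J, 1)
    for _ in range(max_tries):
        if got >= n_draws:
            break
        m = np.eye(J)
        vals = rng.uniform(-1, 1, npairs)
        m[iu] = vals
        m.T[iu] = vals
        evals = np.linalg.eigvalsh(m)
        if evals.min() <= 0:
            continue
        if eta > 1 and rng.uniform() > np.prod(evals) ** (eta - 1):
            continue
        out[got] = m
        got += 1
    if got < n_draws:
        raise RuntimeError("rejection sampler exhausted its proposal budget")
    return out


# -- scale (standard-deviation) priors --------------------------------------

def _scale_dist(family: str, s: float):
    """scipy frozen distribution for each supported SD prior.

    Parameterizations put the central mass near ``s``: half-t/half-normal/
    half-Cauchy use scale s; exponential has mean s; gamma(2) has mean s;
    the lognormal has median s (log-SD .5); uniform is on (0, 2s).
    """
    if family == "half_t_2":
        return _HalfT(2.0, s)
    if family == "half_normal":
        return stats.halfnorm(scale=s)
    if family == "half_cauchy":
        return stats.halfcauchy(scale=s)
    if family == "exponential":
        return stats.expon(scale=s)
    if family == "gamma":
        return stats.gamma(a=2.0, scale=s / 2.0)
    if family == "lognormal":
        return stats.lognorm(s=0.5, scale=s)
    if family == "uniform":
        return stats.uniform(loc=0.0, scale=2.0 * s)
    raise ValueError(
        f"unknown scale family {family!r}; supported: {', '.join(SCALE_FAMILIES)}"
    )


class _HalfT:
    """Positive half of a scaled Student-t distribution."""

    def __init__(self, df: float, scale: float):
        self.df, self.scale = df, scale

    def rvs(self, size=None, random_state=None):
        return np.abs(stats.t.rvs(self.df, scale=self.scale, size=size,
                                  random_state=random_state))

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.log(2.0) + stats.t.logpdf(x, self.df, scale=self.scale)
        return np.where(x > 0, out, -np.inf)

    def ppf(self, q):
        return stats.t.ppf(0.5 + np.asarray(q) / 2.0, self.df, scale=self.scale)


def sample_scale(family: str, s: float, n_draws: int, seed) -> np.ndarray:
    """Positive SD draws from the named scale-prior family."""
    rng = _rng(seed)
    return np.asarray(_scale_dist(family, s).rvs(size=n_draws, random_state=rng))


def scale_logpdf(family: str, s, x) -> np.ndarray:
    """Log prior density of SDs under the named family (elementwise).

    ``s`` may be a scalar or a per-coordinate vector broadcastable with
    ``x``. Closed forms are used (this sits inside Metropolis loops); each
    matches the corresponding sampling distribution in ``sample_scale``.
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if family == "half_t_2":
            out = (-np.log(np.sqrt(2.0) * s)
                   - 1.5 * np.log1p(x ** 2 / (2.0 * s ** 2)))
        elif family == "half_normal":
            out = (np.log(2.0) - np.log(s) - 0.5 * np.log(2.0 * np.pi)
                   - x ** 2 / (2.0 * s ** 2))
        elif family == "half_cauchy":
            out = np.log(2.0 / np.pi) - np.log(s) - np.log1p(x ** 2 / s ** 2)
        elif family == "exponential":
            out = -np.log(s) - x / s
        elif family == "gamma":
            out = np.log(x) - 2.0 * np.log(s / 2.0) - 2.0 * x / s
        elif family == "lognormal":
            sdlog = 0.5
            out = (-np.log(x) - np.log(sdlog) - 0.5 * np.log(2.0 * np.pi)
                   - (np.log(x) - np.log(s)) ** 2 / (2.0 * sdlog ** 2))
        elif family == "uniform":
            out = np.where(x < 2.0 * s, -np.log(2.0 * s), -np.inf)
        else:
            raise ValueError(
                f"unknown scale family {family!r}; "
                f"supported: {', '.join(SCALE_FAMILIES)}"
            )
    return np.where(x > 0, out, -np.inf)


# ---------------------------------------------------------------------------
# Prior visualization panels
# ---------------------------------------------------------------------------

def _norm_hist(x, edges):
    h, _ = np.histogram(x, bins=edges, density=True)
    return h


def prior_panels(draws, n_bins: int = 61, window: float = 0.2) -> dict:
    """Gridded summaries of a covariance (or sd, rho) prior sample.

    Parameters
    ----------
    draws
        Either an (n, J, J) stack of covariance draws, or a tuple
        ``(sd, rho)`` of (n, J) SDs and (n, J, J) correlations (the LKJ
        case, where the two are drawn separately).
    n_bins
        Number of histogram bins on [-1, 1] for correlations.
    window
        Conditioning windows are the bottom/top ``window`` quantiles of the
        conditioning variable.

    Returns a dict with normalized histograms ("marginal_rho12",
    "rho12_given_low_sd1", "rho12_given_high_sd1", "rho12_given_low_rho13",
    "rho12_given_high_rho13"), 2-D density grids ("sd1_rho12_grid",
    "rho12_rho13_grid"), and the bin edges.
    """
    if isinstance(draws, tuple):
        sd, rho = draws
        sd = np.asarray(sd, dtype=float)
        rho = np.asarray(rho, dtype=float)
    else:
        sd, rho = corr_from_cov(np.asarray(draws, dtype=float))
    n = rho.shape[0]
    if n < 10_000:
        raise ValueError("need at least 10^4 draws for stable panels")
    J = rho.shape[-1]
    r12 = rho[:, 0, 1]
    sd1 = sd[:, 0]
    r_edges = np.linspace(-1, 1, n_bins + 1)
    out = {"rho_bin_edges": r_edges}
    out["marginal_rho12"] = _norm_hist(r12, r_edges)

    lo, hi = np.quantile(sd1, [window, 1 - window])
    out["rho12_given_low_sd1"] = _norm_hist(r12[sd1 <= lo], r_edges)
    out["rho12_given_high_sd1"] = _norm_hist(r12[sd1 >= hi], r_edges)
    sd_edges = np.linspace(np.quantile(sd1, 0.001), np.quantile(sd1, 0.95),
                           n_bins + 1)
    grid, _, _ = np.histogram2d(sd1, r12, bins=[sd_edges, r_edges],
                                density=True)
    out["sd_bin_edges"] = sd_edges
    out["sd1_rho12_grid"] = grid

    if J >= 3:
        r13 = rho[:, 0, 2]
        lo13, hi13 = np.quantile(r13, [window, 1 - window])
        out["rho12_given_low_rho13"] = _norm_hist(r12[r13 <= lo13], r_edges)
        out["rho12_given_high_rho13"] = _norm_hist(r12[r13 >= hi13], r_edges)
        grid2, _, _ = np.histogram2d(r12, r13, bins=[r_edges, r_edges],
                                     density=True)
        out["rho12_rho13_grid"] = grid2
    return out


def panels_to_csv(panels: dict, directory) -> None:
    """Serialize each panel array to a CSV grid under ``directory``."""
    import os
    import pandas as pd

    os.makedirs(directory, exist_ok=True)
    for key, val in panels.items():
        arr = np.asarray(val)
        df = pd.DataFrame(arr if arr.ndim == 2 else arr[None])
        df.to_csv(os.path.join(directory, f"{key}.csv"), index=False)
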