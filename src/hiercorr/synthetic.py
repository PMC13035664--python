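"""Synthetic data generation for correlation-recovery studies.

Every dataset the simulation studies use is generated here: multivariate
normal "manifest" scores (one observation per individual and task),
hierarchical trial-level data (L noisy replicates around each individual's
true score), and two-condition contrast designs in which the quantity of
interest is the within-task condition difference (e.g., a Stroop effect).

The generative model throughout is

    theta_i ~ N_J(mu, D(sigma) rho D(sigma))          (true scores)
    Y_ijl | theta_ij ~ N(theta_ij, tau_j^2)           (hierarchical trials)
    Y_ijkl ~ N(alpha_ij + x_k * theta_ij, tau_j^2)    (contrast trials)

with x_k in {-.5, +.5}, so theta_ij is exactly the condition-2 minus
condition-1 difference for person i in task j.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GroundTruth",
    "TrialDataset",
    "ManifestDataset",
    "make_ground_truth",
    "make_manifest_truth",
    "sample_true_scores",
    "sample_trials",
    "sample_manifest",
]

_PSD_TOL = -1e-10

# Study-wide constants: every simulated experiment has 200 individuals, and
# hierarchical designs use a deliberately low 20 trials per cell so that
# trial noise matters; contrast designs use 150 trials per cell.
_DEFAULT_I = 200
_DEFAULT_L_HIER = 20
_DEFAULT_L_CONTRAST = 150


def _as_corr(rho_value, J: int) -> np.ndarray:
    """Expand a scalar or matrix correlation specification to a JxJ matrix."""
    if np.isscalar(rho_value):
        r = float(rho_value)
        m = np.full((J, J), r)
        np.fill_diagonal(m, 1.0)
        return m
    m = np.asarray(rho_value, dtype=float)
    if m.shape != (J, J):
        raise ValueError(f"correlation matrix must be {J}x{J}, got {m.shape}")
    return m


def check_correlation(rho: np.ndarray, *, name: str = "rho") -> np.ndarray:
    """Validate symmetry, unit diagonal and positive semidefiniteness."""
    rho = np.asarray(rho, dtype=float)
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(rho, rho.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(rho), 1.0, atol=1e-12):
        raise ValueError(f"{name} must have unit diagonal")
    evals = np.linalg.eigvalsh(rho)
    if evals.min() < _PSD_TOL:
        raise ValueError(
            f"{name} is not positive semidefinite: minimum eigenvalue "
            f"{evals.min():.3e} < {_PSD_TOL:.0e}"
        )
    return rho


@dataclass(frozen=True)
class GroundTruth:
    """Complete generative specification of one simulated experiment.

    ``design`` selects the observation model: ``manifest`` (one score per
    individual x task), ``hierarchical`` (L replicates per cell), or
    ``contrast`` (two conditions per task, L replicates per condition, with
    per-person intercepts drawn from N(intercept_mean, intercept_sd^2)).
    """

    mu: np.ndarray
    sigma: np.ndarray
    rho: np.ndarray
    tau: np.ndarray
    n_individuals: int = _DEFAULT_I
    n_trials: int = _DEFAULT_L_HIER
    design: str = "hierarchical"
    intercept_mean: float = 600.0
    intercept_sd: float = 100.0
    contrast_codes: tuple[float, float] = (-0.5, 0.5)

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        object.__setattr__(self, "tau", np.asarray(self.tau, dtype=float))
        object.__setattr__(self, "rho", check_correlation(self.rho))
        J = self.mu.size
        if self.sigma.size != J or self.tau.size != J or self.rho.shape != (J, J):
            raise ValueError("mu, sigma, tau, rho have inconsistent sizes")
        if (self.sigma < 0).any() or (self.tau < 0).any():
            raise ValueError("standard deviations must be nonnegative")
        if self.design not in ("manifest", "hierarchical", "contrast"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_individuals < 1 or self.n_trials < 1:
            raise ValueError("counts must be positive")
        if self.design == "contrast" and set(self.contrast_codes) != {-0.5, 0.5}:
            raise ValueError("contrast codes must be -.5 and +.5")

    @property
    def n_tasks(self) -> int:
        return self.mu.size

    @property
    def covariance(self) -> np.ndarray:
        """Sigma = D(sigma) rho D(sigma)."""
        return self.rho * np.outer(self.sigma, self.sigma)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("mu", "sigma", "tau"):
            d[k] = np.asarray(d[k]).tolist()
        d["rho"] = np.asarray(d["rho"]).tolist()
        d["contrast_codes"] = list(self.contrast_codes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["contrast_codes"] = tuple(d.get("contrast_codes", (-0.5, 0.5)))
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "GroundTruth":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(source)
        return cls.from_dict(d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls.from_dict(json.loads(text))


@dataclass
class TrialDataset:
    """Long-format trial-level observations.

    ``table`` has columns ``individual``, ``task``, ``condition`` (pandas NA
    for non-contrast designs), ``replicate``, ``score``; ids are dense and
    1-based. ``ground_truth`` is attached when the data are synthetic.
    """

    table: pd.DataFrame
    ground_truth: GroundTruth | None = None

    def __post_init__(self):
        required = {"individual", "task", "replicate", "score"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if "condition" not in self.table.columns:
            self.table = self.table.assign(condition=pd.NA)
        if not np.isfinite(self.table["score"].to_numpy(dtype=float)).all():
            raise ValueError("scores must be finite")

    @property
    def has_conditions(self) -> bool:
        return self.table["condition"].notna().any()

    @property
    def n_individuals(self) -> int:
        return int(self.table["individual"].max())

    @property
    def n_tasks(self) -> int:
        return int(self.table["task"].max())

    def validate_dense(self) -> None:
        """Every (individual, task) cell must be nonempty with dense ids."""
        I, J = self.n_individuals, self.n_tasks
        cells = self.table.groupby(["individual", "task"]).size()
        if len(cells) != I * J:
            raise ValueError("missing (individual, task) cells")

    def cell_stats(self):
        """Per-cell count, sum, and sum of squares (and condition if present).

        Returns a DataFrame indexed by individual, task (, condition).
        """
        keys = ["individual", "task"]
        if self.has_conditions:
            keys.append("condition")
        g = self.table.groupby(keys)["score"]
        out = pd.DataFrame({"n": g.size(), "sum": g.sum(),
                            "sumsq": g.apply(lambda s: float(np.sum(s.to_numpy() ** 2)))})
        return out

    def subset_tasks(self, tasks) -> "TrialDataset":
        """Restrict to a subset of tasks, renumbering them 1..len(tasks)."""
        tasks = list(tasks)
        tab = self.table[self.table["task"].isin(tasks)].copy()
        remap = {t: k + 1 for k, t in enumerate(tasks)}
        tab["task"] = tab["task"].map(remap)
        gt = None
        if self.ground_truth is not None:
            idx = [t - 1 for t in tasks]
            g = self.ground_truth
            gt = GroundTruth(
                mu=g.mu[idx], sigma=g.sigma[idx],
                rho=g.rho[np.ix_(idx, idx)], tau=g.tau[idx],
                n_individuals=g.n_individuals, n_trials=g.n_trials,
                design=g.design, intercept_mean=g.intercept_mean,
                intercept_sd=g.intercept_sd, contrast_codes=g.contrast_codes,
            )
        return TrialDataset(tab.reset_index(drop=True), gt)

    def to_csv(self, path=None):
        cols = ["individual", "task", "condition", "replicate", "score"]
        out = self.table[cols]
        if path is None:
            buf = io.StringIO()
            out.to_csv(buf, index=False)
            return buf.getvalue()
        out.to_csv(path, index=False)
        return None

    @classmethod
    def from_csv(cls, source) -> "TrialDataset":
        tab = pd.read_csv(source)
        if "condition" in tab.columns:
            tab["condition"] = tab["condition"].astype("Int64")
        return cls(tab)


@dataclass
class ManifestDataset:
    """I x J matrix of per-individual scores with no replicate structure."""

    scores: np.ndarray
    provenance: str = "synthetic"
    ground_truth: GroundTruth | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] < 2:
            raise ValueError("scores must be an I x J matrix with J >= 2")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite (no missing cells)")

    @property
    def n_individuals(self) -> int:
        return self.scores.shape[0]

    @property
    def n_tasks(self) -> int:
        return self.scores.shape[1]


# ---------------------------------------------------------------------------
# Ground-truth presets
# ---------------------------------------------------------------------------

def _four_task_corr(named=(0.3, 0.5, 0.7)) -> np.ndarray:
    """Four-task two-factor-style matrix.

    Only rho_12, rho_13, rho_14 are pinned by the study design; the
    remaining entries are completed as rho_23=.3, rho_24=.5, rho_34=.3,
    which keeps the named coefficients exact and the matrix PSD. Downstream
    summaries report named and completed coefficients separately.
    """
    r12, r13, r14 = named
    m = np.array([
        [1.0, r12, r13, r14],
        [r12, 1.0, 0.3, 0.5],
        [r13, 0.3, 1.0, 0.3],
        [r14, 0.5, 0.3, 1.0],
    ])
    return m


def _eight_task_corr(focal: float = 0.8, background: float = 0.2) -> np.ndarray:
    """Eight tasks: a single high focal correlation rho_12, all others low."""
    m = np.full((8, 8), background)
    np.fill_diagonal(m, 1.0)
    m[0, 1] = m[1, 0] = focal
    return m


def make_ground_truth(preset: str, rho_value=None, tau_value=None,
                      **overrides) -> GroundTruth:
    """Build the generative specification for one of the study designs.

    Presets
    -------
    two_task
        I=200, L=20, mu=(.5,.5), sigma=(.1,.1); ``rho_value`` is the single
        correlation (default .5), ``tau_value`` the common trial noise SD
        (default .2).
    four_task
        As two_task with J=4 and the two-factor matrix (rho_12=.3,
        rho_13=.5, rho_14=.7, completed entries documented above).
    eight_task
        J=8 with rho_12=``rho_value`` (default .8) and all other
        off-diagonals .2.
    contrast
        Two-task Stroop-style design: intercepts N(600, 100^2) ms, slope
        means 60 ms, slope SDs 25 ms, slope correlation ``rho_value``
        (default .5), tau=175 ms, 150 trials per individual x task x
        condition.
    """
    if preset == "two_task":
        J = 2
        rho = _as_corr(0.5 if rho_value is None else rho_value, J)
        tau = 0.2 if tau_value is None else float(tau_value)
        base = dict(mu=np.full(J, 0.5), sigma=np.full(J, 0.1), rho=rho,
                    tau=np.full(J, tau), n_individuals=_DEFAULT_I,
                    n_trials=_DEFAULT_L_HIER, design="hierarchical")
    elif preset == "four_task":
        rho = _four_task_corr() if rho_value is None else _as_corr(rho_value, 4)
        tau = 0.2 if tau_value is None else float(tau_value)
        base = dict(mu=np.full(4, 0.5), sigma=np.full(4, 0.1), rho=rho,
                    tau=np.full(4, tau), n_individuals=_DEFAULT_I,
                    n_trials=_DEFAULT_L_HIER, design="hierarchical")
    elif preset == "eight_task":
        if rho_value is None:
            rho = _eight_task_corr()
        elif np.isscalar(rho_value):
            rho = _eight_task_corr(focal=float(rho_value))
        else:
            rho = _as_corr(rho_value, 8)
        tau = 0.4 if tau_value is None else float(tau_value)
        base = dict(mu=np.full(8, 0.5), sigma=np.full(8, 0.1), rho=rho,
                    tau=np.full(8, tau), n_individuals=_DEFAULT_I,
                    n_trials=_DEFAULT_L_HIER, design="hierarchical")
    elif preset == "contrast":
        J = 2
        rho = _as_corr(0.5 if rho_value is None else rho_value, J)
        tau = 175.0 if tau_value is None else float(tau_value)
        base = dict(mu=np.full(J, 60.0), sigma=np.full(J, 25.0), rho=rho,
                    tau=np.full(J, tau), n_individuals=_DEFAULT_I,
                    n_trials=_DEFAULT_L_CONTRAST, design="contrast",
                    intercept_mean=600.0, intercept_sd=100.0)
    else:
        raise ValueError(
            f"unknown preset {preset!r}; expected one of "
            "two_task, four_task, eight_task, contrast"
        )
    base.update(overrides)
    return GroundTruth(**base)


def make_manifest_truth(J: int = 2, pair_rho: float = 0.5,
                        background_rho: float = 0.3, sigma: float = 1.0,
                        n_individuals: int = _DEFAULT_I) -> GroundTruth:
    """Manifest-design truth: J correlated variables, no trial noise.

    With J=10 and pair_rho=.5 this emulates the shape of the anthropometric
    height-weight application (a synthetic stand-in: 10 correlated body-like
    measures, target pair correlation .5 between variables 1 and 2).
    """
    if J == 2:
        rho = _as_corr(pair_rho, 2)
    else:
        rho = np.full((J, J), background_rho)
        np.fill_diagonal(rho, 1.0)
        rho[0, 1] = rho[1, 0] = pair_rho
    return GroundTruth(mu=np.zeros(J), sigma=np.full(J, sigma), rho=rho,
                       tau=np.zeros(J), n_individuals=n_individuals,
                       n_trials=1, design="manifest")


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_true_scores(gt: GroundTruth, seed) -> np.ndarray:
    """Draw the I x J matrix of true scores theta_i ~ N(mu, D(s) rho D(s))."""
    rng = _rng(seed)
    J = gt.n_tasks
    # Cholesky of the correlation (fall back to eigen for semidefinite rho)
    try:
        C = np.linalg.cholesky(gt.rho)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(gt.rho)
        C = V * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((gt.n_individuals, J))
    return gt.mu + (z @ C.T) * gt.sigma


def sample_trials(gt: GroundTruth, theta: np.ndarray, seed) -> TrialDataset:
    """Emit trial-level replicates around true scores.

    Hierarchical designs produce L replicates per (i, j) cell; contrast
    designs produce L replicates per (i, j, k) cell around
    alpha_ij + x_k * theta_ij, with the per-person intercepts alpha_ij drawn
    inside this function.
    """
    rng = _rng(seed)
    theta = np.asarray(theta, dtype=float)
    I, J = theta.shape
    if (I, J) != (gt.n_individuals, gt.n_tasks):
        raise ValueError("theta not conformable with ground truth")
    L = gt.n_trials
    if gt.design == "contrast":
        alpha = rng.normal(gt.intercept_mean, gt.intercept_sd, size=(I, J))
        frames = []
        for k, x in enumerate(sorted(gt.contrast_codes), start=1):
            mean = alpha + x * theta  # I x J
            noise = rng.standard_normal((I, J, L)) * gt.tau[None, :, None]
            scores = mean[:, :, None] + noise
            ii, jj, ll = np.meshgrid(np.arange(1, I + 1), np.arange(1, J + 1),
                                     np.arange(1, L + 1), indexing="ij")
            frames.append(pd.DataFrame({
                "individual": ii.ravel(), "task": jj.ravel(),
                "condition": k, "replicate": ll.ravel(),
                "score": scores.ravel()}))
        tab = pd.concat(frames, ignore_index=True)
        tab["condition"] = tab["condition"].astype("Int64")
        return TrialDataset(tab, gt)

    noise = rng.standard_normal((I, J, L)) * gt.tau[None, :, None]
    scores = theta[:, :, None] + noise
    ii, jj, ll = np.meshgrid(np.arange(1, I + 1), np.arange(1, J + 1),
                             np.arange(1, L + 1), indexing="ij")
    tab = pd.DataFrame({
        "individual": ii.ravel(), "task": jj.ravel(),
        "condition": pd.array([pd.NA] * scores.size, dtype="Int64"),
        "replicate": ll.ravel(), "score": scores.ravel()})
    return TrialDataset(tab, gt)


def sample_manifest(gt: GroundTruth, seed) -> ManifestDataset:
    """One multivariate-normal score per individual (manifest design)."""
    if gt.design != "manifest":
        raise ValueError("sample_manifest requires a manifest-design truth")
    scores = sample_true_scores(gt, seed)
    return ManifestDataset(scores, provenance="synthetic", ground_truth=gt)
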