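"""Replicate-level orchestration of the simulation studies.

A *study* draws fresh data on each replicate, submits the identical data to
every configured estimation method (hierarchical fits under a menu of
covariance priors, the trial-averaging baseline, and the best-case sample
correlation among true scores), and aggregates the per-replicate estimates
into RMSE tables, credible-interval coverage proportions, and smoothed
densities of the posterior means.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import gaussian_kde

from .baselines import average_then_correlate, fisher_ci, pearson
from .priors import IWSpec, LKJSpec, SIWSpec, default_iw
from .samplers import ChainConfig, fit_contrast, fit_hier
from .samplers.results import pair_names
from .synthetic import GroundTruth, make_ground_truth, sample_trials, sample_true_scores

__all__ = [
    "StudyConfig", "StudyResult", "standard_methods", "run_study",
    "rmse_table", "rmse_bootstrap_se", "coverage_table", "mean_density",
    "run_inclusion_study", "inclusion_scatter", "save_study",
]


def standard_methods(J: int, s: float = 0.1, eta: float = 1.0,
                     siw_v: float = 2.0, scale_family: str = "half_t_2",
                     which=("IW", "SIW", "LKJ")) -> dict:
    """Default prior menu: IW(v=J+1, s^2 I), SIW(v=2, s), LKJ(eta) + scales."""
    menu = {
        "IW": lambda: default_iw(J, s),
        "SIW": lambda: SIWSpec(v=siw_v, s=np.full(J, s)),
        "LKJ": lambda: LKJSpec(eta=eta, s=np.full(J, s),
                               scale_family=scale_family),
    }
    return {name: menu[name]() for name in which}


@dataclass
class StudyConfig:
    """Settings for one simulation study.

    ``methods`` maps a display name to a prior spec; each named method is
    fit to the same data on every replicate. Per-replicate RNG streams are
    seeded ``base_seed + replicate`` so studies parallelize and rerun
    deterministically.
    """

    preset: str
    methods: dict
    rho: float | None = None
    tau: float | None = None
    n_replicates: int = 100
    chain: ChainConfig = field(default_factory=ChainConfig)
    base_seed: int = 1
    include_true_scores: bool = True
    include_averaging: bool = True
    overrides: dict = field(default_factory=dict)
    tolerate_failures: bool = False

    def ground_truth(self) -> GroundTruth:
        return make_ground_truth(self.preset, self.rho, self.tau,
                                 **self.overrides)

    def to_yaml(self) -> str:
        d = {
            "preset": self.preset, "rho": self.rho, "tau": self.tau,
            "n_replicates": self.n_replicates, "base_seed": self.base_seed,
            "methods": {k: v.to_dict() for k, v in self.methods.items()},
            "chain": self.chain.__dict__,
        }
        return yaml.safe_dump(d, sort_keys=False)


@dataclass
class StudyResult:
    """Per-replicate estimates plus the generating truth.

    ``replicates`` has one row per (replicate, method, task pair) with the
    point estimate (posterior mean for Bayesian methods), the 95% interval,
    the true coefficient, a coverage flag, and diagnostics summaries.
    """

    replicates: pd.DataFrame
    ground_truth: GroundTruth
    config: StudyConfig
    failures: list = field(default_factory=list)


def _estimate_rows(rep, method, pairs, estimates, intervals, truth, named_row,
                   sample_r, rhat=np.nan, ess=np.nan):
    rows = []
    for p, (a, b) in enumerate(pairs):
        lo, hi = intervals[p]
        t = truth[p]
        rows.append({
            "replicate": rep, "method": method, "pair": f"{a},{b}",
            "task_a": a, "task_b": b, "named": named_row[p],
            "estimate": estimates[p], "lower": lo, "upper": hi,
            "truth": t, "sample_r": sample_r[p],
            "covered": bool(lo <= t <= hi),
            "max_rhat": rhat, "min_ess": ess,
        })
    return rows


def run_study(cfg: StudyConfig) -> StudyResult:
    """Run every replicate of a study; identical data feed every method."""
    gt = cfg.ground_truth()
    J = gt.n_tasks
    pairs = pair_names(J)
    truth = [gt.rho[a - 1, b - 1] for a, b in pairs]
    named = [a == 1 for a, b in pairs]
    is_contrast = gt.design == "contrast"
    rows = []
    failures = []
    for rep in range(cfg.n_replicates):
        seed = cfg.base_seed + rep
        try:
            rng = np.random.default_rng(seed)
            theta = sample_true_scores(gt, rng)
            data = sample_trials(gt, theta, rng)
            # realized true-score sample correlations: the best-case
            # reference (known individuals, infinite trials)
            sample_r = [pearson(theta[:, a - 1], theta[:, b - 1])
                        for a, b in pairs]
            if cfg.include_true_scores:
                ints = [fisher_ci(r, gt.n_individuals) for r in sample_r]
                rows += _estimate_rows(rep, "true_scores", pairs, sample_r,
                                       ints, truth, named, sample_r)
            if cfg.include_averaging:
                ests, ints = [], []
                for a, b in pairs:
                    est = average_then_correlate(data, tasks=(a, b))
                    ests.append(est.r)
                    ints.append((est.lower, est.upper))
                rows += _estimate_rows(rep, "averaging", pairs, ests, ints,
                                       truth, named, sample_r)
            for name, prior in cfg.methods.items():
                ccfg = ChainConfig(**{**cfg.chain.__dict__, "seed": seed})
                fit = (fit_contrast if is_contrast else fit_hier)(data, prior,
                                                                  ccfg)
                ests = [fit.rho_mean((a, b)) for a, b in pairs]
                ints = [fit.rho_interval((a, b)) for a, b in pairs]
                rows += _estimate_rows(rep, name, pairs, ests, ints, truth,
                                       named, sample_r, rhat=fit.max_rhat,
                                       ess=fit.min_ess)
        except Exception as exc:  # noqa: BLE001 - replicate isolation
            if not cfg.tolerate_failures:
                raise
            failures.append({"replicate": rep, "seed": seed, "error": str(exc)})
    return StudyResult(replicates=pd.DataFrame(rows), ground_truth=gt,
                       config=cfg, failures=failures)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _errors(d: pd.DataFrame, reference: str) -> pd.Series:
    if reference == "sample_r":
        return d["estimate"] - d["sample_r"]
    if reference == "population":
        return d["estimate"] - d["truth"]
    raise ValueError("reference must be 'sample_r' or 'population'")


def rmse_table(result: StudyResult, named_only: bool = False,
               reference: str = "sample_r") -> pd.DataFrame:
    """RMSE of point estimates per method and task pair.

    ``reference="sample_r"`` (default) measures deviation from each
    replicate's realized true-score sample correlation — the best-case
    benchmark an estimator could track with the same 200 individuals;
    ``reference="population"`` measures deviation from the generating rho.
    """
    df = result.replicates
    if df["replicate"].nunique() < 2:
        raise ValueError("need at least 2 replicates")
    if named_only:
        df = df[df["named"]]
    g = df.groupby(["method", "pair"], observed=True)
    out = g.apply(
        lambda d: pd.Series({
            "truth": d["truth"].iloc[0],
            "rmse": float(np.sqrt(np.mean(_errors(d, reference) ** 2))),
            "bias": float(np.mean(_errors(d, reference))),
            "n_replicates": int(d["replicate"].nunique()),
        }),
        include_groups=False,
    ).reset_index()
    return out


def rmse_bootstrap_se(errors, n_boot: int = 1000, seed: int = 0) -> float:
    """Bootstrap standard error of an RMSE over replicate errors."""
    e = np.asarray(errors, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, e.size, size=(n_boot, e.size))
    return float(np.std(np.sqrt(np.mean(e[idx] ** 2, axis=1))))


def rmse_cell(result: StudyResult, method: str, pair=(1, 2),
              reference: str = "sample_r"):
    """(rmse, bootstrap SE) for one method and task pair."""
    df = result.replicates
    d = df[(df["method"] == method) & (df["pair"] == f"{pair[0]},{pair[1]}")]
    err = _errors(d, reference).to_numpy()
    return float(np.sqrt(np.mean(err ** 2))), rmse_bootstrap_se(err)


def coverage_table(result: StudyResult, methods=None, pairs=None,
                   pooled: bool = False):
    """Proportion of 95% intervals containing the truth.

    With ``pooled=True`` a single proportion is returned over the selected
    methods and pairs; otherwise a per-(method, pair) table with the list of
    non-covering replicates.
    """
    df = result.replicates
    df = df[~df["method"].isin(["true_scores"])] if methods is None else \
        df[df["method"].isin(methods)]
    if pairs is not None:
        df = df[df["pair"].isin([f"{a},{b}" for a, b in pairs])]
    if pooled:
        return float(df["covered"].mean())
    g = df.groupby(["method", "pair"], observed=True)
    return g.apply(
        lambda d: pd.Series({
            "coverage": float(d["covered"].mean()),
            "n": int(len(d)),
            "non_covering": sorted(d.loc[~d["covered"], "replicate"]),
        }),
        include_groups=False,
    ).reset_index()


def mean_density(result: StudyResult, method: str, pair=(1, 2),
                 grid=None, bw_method="silverman"):
    """Gaussian-kernel density of the per-replicate point estimates.

    Returns (grid, density, reference_density) where the reference is the
    corresponding density for the true-score sample correlations (the
    infinite-trials best case), or None if those were not recorded.
    """
    df = result.replicates
    key = f"{pair[0]},{pair[1]}"
    x = df[(df["method"] == method) & (df["pair"] == key)]["estimate"].to_numpy()
    if x.size < 10:
        raise ValueError("need at least 10 replicates for a density")
    if grid is None:
        grid = np.linspace(-1, 1, 401)
    if np.ptp(x) < 1e-12:
        dens = np.zeros_like(grid)
        dens[np.argmin(np.abs(grid - x[0]))] = 1.0 / (grid[1] - grid[0])
    else:
        dens = gaussian_kde(x, bw_method=bw_method)(grid)
    ref = df[(df["method"] == "true_scores") & (df["pair"] == key)]
    ref_dens = None
    if len(ref) >= 10:
        ref_dens = gaussian_kde(ref["estimate"].to_numpy(),
                                bw_method=bw_method)(grid)
    return grid, dens, ref_dens


# ---------------------------------------------------------------------------
# Inclusion study (bivariate vs. eight-task context)
# ---------------------------------------------------------------------------

def run_inclusion_study(method_factories: dict, n_replicates: int = 100,
                        chain: ChainConfig | None = None, base_seed: int = 1,
                        tau: float = 0.4, s: float = 0.1) -> dict:
    """Fit the Task1-Task2 correlation in isolation and among eight tasks.

    ``method_factories`` maps a name to a callable J -> prior spec so the
    same family can be instantiated at J=2 and J=8. Both analyses see
    exactly the same data (the bivariate analysis uses the first two tasks
    of the eight-task dataset). Returns {name: DataFrame} with per-replicate
    paired estimates and the true-score sample correlation.
    """
    chain = chain or ChainConfig()
    gt = make_ground_truth("eight_task", tau_value=tau)
    recs = {name: [] for name in method_factories}
    for rep in range(n_replicates):
        seed = base_seed + rep
        rng = np.random.default_rng(seed)
        theta = sample_true_scores(gt, rng)
        data8 = sample_trials(gt, theta, rng)
        data2 = data8.subset_tasks([1, 2])
        r_true = pearson(theta[:, 0], theta[:, 1])
        for name, factory in method_factories.items():
            ccfg = ChainConfig(**{**chain.__dict__, "seed": seed})
            fit2 = fit_hier(data2, factory(2), ccfg)
            fit8 = fit_hier(data8, factory(8), ccfg)
            recs[name].append({
                "replicate": rep, "seed": seed, "true_score_r": r_true,
                "bivariate": fit2.rho_mean((1, 2)),
                "eight_task": fit8.rho_mean((1, 2)),
                "truth": gt.rho[0, 1],
            })
    return {name: pd.DataFrame(rows) for name, rows in recs.items()}


def inclusion_scatter(bivariate: pd.DataFrame,
                      multivariate: pd.DataFrame) -> pd.DataFrame:
    """Pair per-replicate estimates from two runs of the same seeds.

    Accepts the per-method frames from :func:`run_inclusion_study` (in which
    case both arguments may be the same frame) or any two frames carrying
    ``replicate``, ``seed`` and an estimate column. Returns the paired frame
    plus a ``displacement`` column (multivariate minus bivariate).
    """
    b = bivariate.set_index("replicate")
    m = multivariate.set_index("replicate")
    if not b.index.equals(m.index) or not (b["seed"] == m["seed"]).all():
        raise ValueError("runs do not share seeds/replicates")
    bcol = "bivariate" if "bivariate" in b else "estimate"
    mcol = "eight_task" if "eight_task" in m else "estimate"
    out = pd.DataFrame({
        "bivariate": b[bcol], "multivariate": m[mcol],
        "true_score_r": b.get("true_score_r"),
    })
    out["displacement"] = out["multivariate"] - out["bivariate"]
    return out.reset_index()


# ---------------------------------------------------------------------------
# Output layout
# ---------------------------------------------------------------------------

def save_study(result: StudyResult, outdir, log_lines=None) -> None:
    """One directory per study: replicates, RMSE, coverage, config, log."""
    os.makedirs(outdir, exist_ok=True)
    result.replicates.to_csv(os.path.join(outdir, "replicates.csv"),
                             index=False)
    rmse_table(result).to_csv(os.path.join(outdir, "rmse.csv"), index=False)
    coverage_table(result).to_csv(os.path.join(outdir, "coverage.csv"),
                                  index=False)
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        fh.write(result.config.to_yaml())
    with open(os.path.join(outdir, "log.txt"), "w") as fh:
        fh.write("\n".join(log_lines or []) + "\n")
        for f in result.failures:
            fh.write(f"FAILED replicate {f['replicate']} (seed {f['seed']}): "
                     f"{f['error']}\n")
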