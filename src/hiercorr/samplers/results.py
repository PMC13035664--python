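"""Containers for posterior draws and fit summaries."""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import bulk_ess, split_rhat

__all__ = ["PosteriorDraws", "FitResult", "pair_names"]


def pair_names(J: int) -> list[tuple[int, int]]:
    """Upper-triangle (1-based) task pairs in row-major order."""
    return [(j + 1, k + 1) for j in range(J) for k in range(j + 1, J)]


@dataclass
class PosteriorDraws:
    """Retained MCMC draws with chain indexing.

    ``mu``, ``sigma``, ``tau`` have shape (chains, draws, J); ``rho`` holds
    the off-diagonal correlations, shape (chains, draws, n_pairs), ordered
    as in :func:`pair_names`. ``theta`` (chains, draws, I, J) is stored only
    when requested. ``model`` tags the observation model and prior family.
    """

    mu: np.ndarray
    sigma: np.ndarray
    tau: np.ndarray
    rho: np.ndarray
    model: str
    theta: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu.shape[1]

    @property
    def J(self) -> int:
        return self.mu.shape[2]

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return pair_names(self.J)

    def scalar_series(self) -> dict[str, np.ndarray]:
        """All monitored scalar parameters as (chains, draws) arrays."""
        out = {}
        for j in range(self.J):
            out[f"mu[{j + 1}]"] = self.mu[:, :, j]
            out[f"sigma[{j + 1}]"] = self.sigma[:, :, j]
            out[f"tau[{j + 1}]"] = self.tau[:, :, j]
        for p, (j, k) in enumerate(self.pairs):
            out[f"rho[{j},{k}]"] = self.rho[:, :, p]
        return out

    def rho_matrix_draws(self) -> np.ndarray:
        """Reassemble full correlation matrices, shape (C, n, J, J)."""
        C, n, _ = self.rho.shape
        J = self.J
        out = np.zeros((C, n, J, J))
        out[..., range(J), range(J)] = 1.0
        for p, (j, k) in enumerate(self.pairs):
            out[..., j - 1, k - 1] = self.rho[..., p]
            out[..., k - 1, j - 1] = self.rho[..., p]
        return out


@dataclass
class FitResult:
    """Posterior draws plus summaries and convergence diagnostics.

    ``rho_summary`` has one row per task pair with the posterior mean and
    the equal-tailed 95% credible interval. ``diagnostics`` maps parameter
    names to split R-hat and bulk ESS; ``acceptance`` holds Metropolis
    acceptance rates (LKJ fits only).
    """

    draws: PosteriorDraws
    rho_summary: pd.DataFrame
    diagnostics: dict
    acceptance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @classmethod
    def from_draws(cls, draws: PosteriorDraws, acceptance=None,
                   compute_diagnostics: bool = True,
                   warnings_: list | None = None) -> "FitResult":
        rows = []
        for p, (j, k) in enumerate(draws.pairs):
            x = draws.rho[:, :, p].ravel()
            lo, hi = np.quantile(x, [0.025, 0.975])
            rows.append({"pair": f"{j},{k}", "task_a": j, "task_b": k,
                         "mean": float(x.mean()), "lower": float(lo),
                         "upper": float(hi)})
        summary = pd.DataFrame(rows)
        diags = {}
        if compute_diagnostics:
            for name, series in draws.scalar_series().items():
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    diags[name] = {"rhat": split_rhat(series),
                                   "ess_bulk": bulk_ess(series)}
        return cls(draws=draws, rho_summary=summary, diagnostics=diags,
                   acceptance=dict(acceptance or {}),
                   warnings=list(warnings_ or []))

    @property
    def max_rhat(self) -> float:
        vals = [d["rhat"] for d in self.diagnostics.values()
                if np.isfinite(d["rhat"])]
        return float(max(vals)) if vals else float("nan")

    @property
    def min_ess(self) -> float:
        vals = [d["ess_bulk"] for d in self.diagnostics.values()
                if np.isfinite(d["ess_bulk"])]
        return float(min(vals)) if vals else float("nan")

    def rho_mean(self, pair: tuple[int, int] = (1, 2)) -> float:
        row = self.rho_summary[self.rho_summary["pair"] == f"{pair[0]},{pair[1]}"]
        return float(row["mean"].iloc[0])

    def rho_interval(self, pair: tuple[int, int] = (1, 2)) -> tuple[float, float]:
        row = self.rho_summary[self.rho_summary["pair"] == f"{pair[0]},{pair[1]}"]
        return float(row["lower"].iloc[0]), float(row["upper"].iloc[0])

    # -- serialization ----------------------------------------------------

    def draws_to_csv(self, path=None):
        """Long-format draws CSV: chain, iteration, parameter, value."""
        frames = []
        for name, series in self.draws.scalar_series().items():
            C, n = series.shape
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(1, C + 1), n),
                "iteration": np.tile(np.arange(1, n + 1), C),
                "parameter": name,
                "value": series.ravel()}))
        out = pd.concat(frames, ignore_index=True)
        if path is None:
            buf = io.StringIO()
            out.to_csv(buf, index=False)
            return buf.getvalue()
        out.to_csv(path, index=False)
        return None

    def diagnostics_to_json(self, path=None):
        payload = {"model": self.draws.model,
                   "max_rhat": self.max_rhat,
                   "min_ess_bulk": self.min_ess,
                   "acceptance": self.acceptance,
                   "warnings": self.warnings,
                   "parameters": self.diagnostics}
        text = json.dumps(payload, indent=2, default=float)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None
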