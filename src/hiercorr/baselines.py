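"""Classical correlation estimators used as comparison baselines.

The conventional analysis averages replicates into individual-by-task
scores, correlates the averages (Pearson), and attaches Fisher z-transform
confidence intervals. Trial noise survives the averaging and attenuates the
expected sample correlation by the multiplicative factor

    E(rho_hat) ~= [ s1 s2 / (sqrt(s1^2 + t1^2) sqrt(s2^2 + t2^2)) ] rho

where s are between-individual SDs and t the effective per-score error SDs
(tau / sqrt(L) for L-trial averages).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic import TrialDataset

__all__ = ["CorrEstimate", "pearson", "fisher_ci",
           "average_then_correlate", "attenuation_coefficient"]


@dataclass(frozen=True)
class CorrEstimate:
    """Point estimate and confidence interval for one correlation."""

    r: float
    lower: float
    upper: float
    n: int
    method: str = "pearson"

    def __post_init__(self):
        if not (self.lower <= self.r <= self.upper):
            raise ValueError("interval must bracket the point estimate")

    def covers(self, rho: float) -> bool:
        return self.lower <= rho <= self.upper


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = xc @ xc
    vy = yc @ yc
    if vx == 0 or vy == 0:
        raise ValueError("zero variance input")
    return float((xc @ yc) / np.sqrt(vx * vy))


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval: tanh(atanh r +- z/sqrt(n-3))."""
    if n <= 3:
        raise ValueError("need n > 3")
    if abs(r) >= 1.0:
        warnings.warn("|r| = 1: degenerate interval", RuntimeWarning)
        return (float(r), float(r))
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def average_then_correlate(data: TrialDataset, tasks=(1, 2),
                           level: float = 0.95) -> CorrEstimate:
    """Average replicates per cell, then correlate two tasks.

    For contrast designs the per-individual score is the condition-2 minus
    condition-1 mean difference (the empirical contrast), mirroring the
    model's definition of theta under +-.5 codes.
    """
    tab = data.table
    a, b = tasks
    if data.has_conditions:
        g = (tab.groupby(["individual", "task", "condition"], observed=True)
             ["score"].mean().unstack("condition"))
        conds = sorted(c for c in g.columns)
        if len(conds) != 2:
            raise ValueError("contrast averaging needs exactly 2 conditions")
        scores = (g[conds[1]] - g[conds[0]]).unstack("task")
    else:
        scores = (tab.groupby(["individual", "task"], observed=True)["score"]
                  .mean().unstack("task"))
    x = scores[a].to_numpy()
    y = scores[b].to_numpy()
    r = pearson(x, y)
    lo, hi = fisher_ci(r, len(x), level=level)
    return CorrEstimate(r=r, lower=lo, upper=hi, n=len(x), method="averaging")


def attenuation_coefficient(sigma, tau, L: int = 1) -> float:
    """Multiplicative attenuation factor for a correlation of noisy scores.

    ``sigma`` and ``tau`` are (length-2) between-individual and trial SDs;
    ``L`` is the number of trials averaged per score, so the effective error
    variance per averaged score is tau^2 / L.
    """
    s = np.asarray(sigma, dtype=float)
    t = np.asarray(tau, dtype=float)
    if (s <= 0).any() or (t < 0).any() or L < 1:
        raise ValueError("need sigma > 0, tau >= 0, L >= 1")
    eff = t ** 2 / L
    return float(np.prod(s) / np.sqrt(np.prod(s ** 2 + eff)))
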