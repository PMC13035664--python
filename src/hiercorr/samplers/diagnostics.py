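"""Convergence diagnostics: rank-normalized split R-hat and bulk ESS.

Thin wrappers around arviz, which implements the rank-normalized
split-chain R-hat and the bulk effective sample size (autocorrelation
summation with Geyer's initial-monotone truncation). Inputs are plain
arrays shaped (n_chains, n_draws) or 1-D (a single chain, split in half).
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["split_rhat", "bulk_ess"]


def _to_chains(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        n = x.size // 2
        if n < 10:
            raise ValueError("need at least 20 draws to form split halves")
        x = x[: 2 * n].reshape(2, n)
    elif x.ndim != 2:
        raise ValueError("draws must be 1-D or (chains, draws)")
    return x


def split_rhat(draws) -> float:
    """Rank-normalized split R-hat; ~1 indicates convergence.

    Constant chains yield NaN with a warning rather than an exception.
    """
    x = _to_chains(draws)
    if x.shape[1] < 10:
        raise ValueError("need chains of length >= 10")
    if np.allclose(x, x.flat[0]):
        warnings.warn("constant chains: R-hat undefined", RuntimeWarning)
        return float("nan")
    # arviz needs >= 2 chains; split each chain into halves explicitly so a
    # single chain still yields the split diagnostic
    n = x.shape[1] // 2
    x = x[:, : 2 * n].reshape(x.shape[0] * 2, n)
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(x, method="rank"))


def bulk_ess(draws) -> float:
    """Rank-normalized bulk effective sample size.

    Values above the raw draw count are possible for antithetic chains and
    are reported as computed.
    """
    x = _to_chains(draws)
    if x.size < 50:
        raise ValueError("need at least 50 draws")
    if np.allclose(x, x.flat[0]):
        warnings.warn("constant chains: ESS undefined", RuntimeWarning)
        return float("nan")
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(x, method="bulk"))
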