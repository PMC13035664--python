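"""Manifest-model robustness to the prior scale (synthetic stand-in).

A 200-person sample of correlated "body-measure-like" variables (target
pair correlation .5) is analyzed as a bivariate problem and as a
ten-variable problem, with the prior scale swept from 0.1x to 10x the true
SD. With negligible measurement error all three priors track the Pearson
estimate closely; the IW drifts slightly low at 10x scale and the LKJ
slightly low when eight extra variables are included.

Output: results/manifest_scale.csv
"""

import argparse
import os

import numpy as np
import pandas as pd

from hiercorr.baselines import fisher_ci, pearson
from hiercorr.priors import LKJSpec, SIWSpec, default_iw
from hiercorr.samplers import ChainConfig, fit_manifest
from hiercorr.synthetic import make_manifest_truth, sample_manifest


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--burn", type=int, default=500)
    ap.add_argument("--keep", type=int, default=1500)
    ap.add_argument("--out", default="results/manifest_scale.csv")
    args = ap.parse_args()

    rows = []
    for label, J in [("exclude", 2), ("include", 10)]:
        gt = make_manifest_truth(J=J, pair_rho=0.5)
        ds = sample_manifest(gt, args.seed)
        r = pearson(ds.scores[:, 0], ds.scores[:, 1])
        lo, hi = fisher_ci(r, ds.n_individuals)
        rows.append(dict(context=label, scale_mult=np.nan, method="Pearson",
                         mean=r, lower=lo, upper=hi))
        for mult in (0.1, 1.0, 10.0):
            s = 1.0 * mult  # true SD is 1
            menu = {"IW": default_iw(J, s), "SIW": SIWSpec(s=np.full(J, s)),
                    "LKJ": LKJSpec(s=np.full(J, s))}
            for name, spec in menu.items():
                cfg = ChainConfig(n_burn=args.burn, n_keep=args.keep,
                                  seed=args.seed)
                fit = fit_manifest(ds, spec, cfg)
                lo, hi = fit.rho_interval()
                rows.append(dict(context=label, scale_mult=mult, method=name,
                                 mean=fit.rho_mean(), lower=lo, upper=hi))
                print(f"{label:8s} scale x{mult:4} {name}: "
                      f"{fit.rho_mean():.2f} [{lo:.2f}, {hi:.2f}]")
    os.makedirs(os.path.dirname(args.out), exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
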