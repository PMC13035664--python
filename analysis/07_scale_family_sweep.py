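"""Robustness of the LKJ posterior to the SD-prior family (Study 5).

The LKJ decouples correlation from scale, so the shape of the prior on the
standard deviations (half-t, half-normal, half-Cauchy, exponential, gamma,
lognormal, uniform — all centered near the true scale .1) should barely
move the posterior correlations. Exports per-family posterior-mean
distributions for the four-task design at tau=.4.

Output: results/study5/estimates_by_family.csv
"""

import argparse
import os

import numpy as np
import pandas as pd

from hiercorr.harness import StudyConfig, run_study
from hiercorr.priors import SCALE_FAMILIES, LKJSpec
from hiercorr.samplers import ChainConfig


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--replicates", type=int, default=12)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--burn", type=int, default=400)
    ap.add_argument("--keep", type=int, default=1200)
    ap.add_argument("--out", default="results/study5")
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    rows = []
    for fam in SCALE_FAMILIES:
        cfg = StudyConfig(
            preset="four_task", tau=0.4,
            methods={"LKJ": LKJSpec(s=np.full(4, 0.1), scale_family=fam)},
            n_replicates=args.replicates, base_seed=args.seed,
            chain=ChainConfig(n_burn=args.burn, n_keep=args.keep))
        res = run_study(cfg)
        df = res.replicates
        d = df[(df["method"] == "LKJ")]
        for _, r in d.iterrows():
            rows.append(dict(family=fam, replicate=r["replicate"],
                             pair=r["pair"], estimate=r["estimate"],
                             truth=r["truth"]))
        m12 = d[d["pair"] == "1,2"]["estimate"].mean()
        m14 = d[d["pair"] == "1,4"]["estimate"].mean()
        print(f"{fam:12s}: mean rho12 estimate {m12:.3f} "
              f"(truth .3), rho14 {m14:.3f} (truth .7)")
    pd.DataFrame(rows).to_csv(f"{args.out}/estimates_by_family.csv",
                              index=False)
    print(f"wrote {args.out}/estimates_by_family.csv")


if __name__ == "__main__":
    main()
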