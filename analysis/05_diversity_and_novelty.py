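#!/usr/bin/env python
"""Univariate statistics: diversity, group contrasts, novelty regressions.

Shannon diversity of per-sample class counts compared across tectonic
settings (Kruskal--Wallis, Benjamini--Hochberg), the volcanic-arc-vs-others
contrast on NRPS proportions (Wilcoxon rank-sum), Dunn's post-hoc on
terpene proportions (Holm), and ordinary least-squares regressions of
per-sample minimum novelty on environmental covariates.
"""

import argparse
from pathlib import Path

import pandas as pd

from thermobgc import pipeline


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run-dir", type=Path, default=Path("results/study"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--config", type=Path, default=None)
    args = ap.parse_args()

    res = pipeline.run_stats(args.run_dir, pipeline.load_config(args.config), seed=args.seed)

    print(f"Shannon H (class counts): {res['shannon_mean']:.2f} +/- {res['shannon_sd']:.2f}")
    print("group tests (BH-adjusted):")
    for t in res["group_tests"]:
        print(f"  {t['test']:>30}: {t['statistic_name']} = {t['statistic']:.2f}, "
              f"adj. p = {t['p_adjusted']:.3g} {t['stars']}")
    regs = pd.DataFrame(res["novelty_regressions"])
    ct = regs[regs["covariate"] == "crustal_thickness"]
    print("minimum novelty vs crustal thickness (OLS):")
    for _, r in ct.iterrows():
        print(f"  {r['bgc_class']:>8}: slope = {r['slope']:+.4f}, R^2 = {r['r_squared']:.3f}, "
              f"p = {r['p_value']:.3g} (n = {int(r['n'])})")
    print(f"tables written to {Path(args.run_dir) / 'stats'}")


if __name__ == "__main__":
    main()
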