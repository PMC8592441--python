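#!/usr/bin/env python
"""Pembrolizumab price analyses.

(1) Deterministic threshold: the unit price (and percent reduction from
the 2020 list price of $49.39/mg) at which the base-case ICER meets the
$100,000/QALY willingness-to-pay threshold, found by bisection.
(2) Probabilistic sweep: the PSA probability of cost-effectiveness across
a grid of prices, locating the price below which it exceeds one half.
"""

import argparse
import json
from pathlib import Path

import numpy as np

import sclc_cea as sc


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-iter", type=int, default=500)
    parser.add_argument("--step", type=float, default=1.0)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    cfg = sc.make_base_case_config()
    wtp = cfg["model"]["wtp"]
    pt = sc.price_threshold(cfg, target_wtp=wtp)
    print(
        f"the base-case ICER reaches {wtp:,.0f}/QALY at a pembrolizumab price of "
        f"{pt.price:.2f} $/mg, a {pt.pct_reduction:.1f}% reduction from {pt.base_price:.2f} $/mg"
    )

    grid = np.arange(0.0, pt.base_price + args.step, args.step)
    sweep = sc.psa_price_sweep(cfg, grid, wtp=wtp, n_iter=args.n_iter, seed=args.seed)
    above = sweep.loc[sweep["probability"] > 0.5, "price"]
    psa_price = float(above.max()) if not above.empty else None
    if psa_price is None:
        print("PSA: the probability of cost-effectiveness never exceeds 1/2 on the grid")
    else:
        print(f"PSA: P(cost-effective) exceeds 1/2 for prices up to {psa_price:.2f} $/mg")

    args.out_dir.mkdir(parents=True, exist_ok=True)
    sweep_path = args.out_dir / "price_sweep.tsv"
    sweep.to_csv(sweep_path, sep="\t", index=False, float_format="%.4f")
    with open(args.out_dir / "price_threshold.json", "w") as fh:
        json.dump(
            {
                "target_wtp": wtp,
                "threshold_price_per_mg": pt.price,
                "pct_reduction": pt.pct_reduction,
                "base_price_per_mg": pt.base_price,
                "psa_majority_price_per_mg": psa_price,
                "seed": args.seed,
                "n_iter": args.n_iter,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    print(f"wrote {sweep_path}")


if __name__ == "__main__":
    main()
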