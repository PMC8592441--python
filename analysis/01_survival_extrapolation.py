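#!/usr/bin/env python
"""Survival extrapolation step: emulate digitized KM curves and pick a law.

The trial published OS follow-up of about 33 months and PFS follow-up of
about 21 months per arm. This script generates synthetic "digitized" curve
points from the base-case log-logistic laws over those windows (standing in
for the GetData digitization of the published figures), fits all four
candidate families to each curve, and tabulates AIC/BIC and the selected
family, plus the implied median survival of each fitted OS law.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import sclc_cea as sc

MONTHS_PER_CYCLE = 21.0 / (365.25 / 12.0)
FOLLOWUP_CYCLES = {"os": 33.0 / MONTHS_PER_CYCLE, "pfs": 21.0 / MONTHS_PER_CYCLE}
FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic")


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    parser.add_argument("--noise-sd", type=float, default=0.01)
    args = parser.parse_args()

    cfg = sc.make_base_case_config()
    rows = []
    for arm in ("pembro_ep", "placebo_ep"):
        for endpoint, followup in FOLLOWUP_CYCLES.items():
            node = cfg["survival"][arm][endpoint]
            true = sc.SurvivalParams(node["family"], (node["theta"], node["gamma"]))
            spec = sc.SyntheticCohortSpec(
                params=true,
                censor_time=followup,
                seed=args.seed,
                grid=tuple(np.linspace(followup / 30, followup, 30)),
                noise_sd=args.noise_sd,
            )
            points = sc.digitized_points(spec)
            fits = [sc.fit_km_points(points, fam) for fam in FAMILIES]
            best = sc.select_distribution(fits)
            for fit in fits:
                rows.append(
                    {
                        "arm": arm,
                        "endpoint": endpoint,
                        "family": fit.family.value,
                        "params": "; ".join(f"{p:.6f}" for p in fit.params.params),
                        "loglik": fit.loglik,
                        "aic": fit.aic,
                        "bic": fit.bic,
                        "sse": fit.sse,
                        "selected": fit.family == best,
                    }
                )
            sel = [r for r in rows if r["arm"] == arm and r["endpoint"] == endpoint and r["selected"]][0]
            print(f"{arm} {endpoint}: selected {sel['family']} (AIC {sel['aic']:.1f})")
            if endpoint == "os":
                med = sc.median_survival(true) * MONTHS_PER_CYCLE
                print(f"  true-law OS median: {med:.1f} months")

    table = pd.DataFrame(rows)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    out = args.out_dir / "survival_fits.tsv"
    table.to_csv(out, sep="\t", index=False, float_format="%.4f")
    n_correct = table.loc[table["selected"], "family"].eq("loglogistic").sum()
    print(f"log-logistic selected for {n_correct}/4 curves; wrote {out}")


if __name__ == "__main__":
    main()
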