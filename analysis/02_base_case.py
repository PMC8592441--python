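#!/usr/bin/env python
"""Deterministic base case: two-arm Markov run, costs, QALYs and the ICER.

Writes the base-case results table (published-table layout), the per-cycle
cohort traces and a run manifest under results/.
"""

import argparse
from pathlib import Path

import sclc_cea as sc
from sclc_cea.reporting import write_report


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    cfg = sc.make_base_case_config()
    result = sc.evaluate(cfg)
    i, c = result.intervention, result.comparator
    print(f"{'':28s}{i.arm:>14s}{c.arm:>14s}{'diff':>12s}")
    print(f"{'LYs':28s}{i.ly.total:14.2f}{c.ly.total:14.2f}{result.d_ly:12.2f}")
    print(f"{'QALYs':28s}{i.qaly.total:14.2f}{c.qaly.total:14.2f}{result.d_qaly:12.2f}")
    print(f"{'Costs ($US)':28s}{i.cost:14,.0f}{c.cost:14,.0f}{result.d_cost:12,.0f}")
    print(f"ICER: {result.icer_per_qaly:,.0f} $/QALY ({result.icer_per_ly:,.0f} $/LY)")
    wtp = cfg["model"]["wtp"]
    nmb = sc.net_monetary_benefit(result, wtp)
    verdict = "cost-effective" if nmb > 0 else "not cost-effective"
    print(f"At WTP {wtp:,.0f}/QALY the combination is {verdict} (incremental NMB {nmb:,.0f}).")

    paths = write_report(result, cfg, args.out_dir)
    for p in paths:
        print(f"wrote {p}")


if __name__ == "__main__":
    main()
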