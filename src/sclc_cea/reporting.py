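"""Report writing: base-case results table, trace export and run manifest."""

from __future__ import annotations

import datetime
from pathlib import Path

import pandas as pd

from . import __version__
from .cea import CEAResult
from .config import RunManifest, config_hash
from .costs import CATEGORIES

_CATEGORY_LABELS = {
    "first_line_acquisition": "1st-line drug acquisition costs",
    "second_line_acquisition": "2nd-line drug acquisition costs",
    "drug_administration": "Drug administration cost",
    "ae_first_line": "AEs management (first-line)",
    "ae_second_line": "AEs management (second-line)",
    "followup_visit": "Follow-up visit",
    "supportive_care": "Supportive care",
    "death": "Death cost",
}


def results_table(result: CEAResult) -> pd.DataFrame:
    """Base-case results in the published table layout (one row per outcome)."""
    i, c = result.intervention, result.comparator
    rows = [
        ("LYs", i.ly.total, c.ly.total),
        ("LYs, PFS state", i.ly.pfs, c.ly.pfs),
        ("LYs, PS state", i.ly.ps, c.ly.ps),
        ("QALYs", i.qaly.total, c.qaly.total),
        ("QALYs, PFS state", i.qaly.pfs, c.qaly.pfs),
        ("QALYs, PS state", i.qaly.ps, c.qaly.ps),
        ("Costs, $US", i.cost, c.cost),
    ]
    for cat in CATEGORIES:
        rows.append((_CATEGORY_LABELS[cat], i.cost_breakdown[cat], c.cost_breakdown[cat]))
    df = pd.DataFrame(rows, columns=["outcome", i.arm, c.arm])
    df["difference"] = df[i.arm] - df[c.arm]
    icer_rows = pd.DataFrame(
        [
            ("ICER per LY, $US", "", "", _fmt_icer(result.icer_per_ly, result)),
            ("ICER per QALY, $US", "", "", _fmt_icer(result.icer_per_qaly, result)),
        ],
        columns=df.columns,
    )
    return pd.concat([df, icer_rows], ignore_index=True)


def _fmt_icer(icer, result: CEAResult):
    if icer is None:
        return "dominated" if result.dominated else "dominant" if result.dominant else "undefined"
    return icer


def check_breakdown(result: CEAResult, tol: float = 1e-6):
    for arm in (result.intervention, result.comparator):
        if abs(sum(arm.cost_breakdown.values()) - arm.cost) > tol:
            raise AssertionError(f"cost breakdown does not sum to total for {arm.arm}")


def write_report(
    result: CEAResult,
    cfg: dict,
    out_dir,
    seed: int | None = None,
    extra_tables: dict | None = None,
) -> list[Path]:
    """Write the results table (TSV), traces and a run manifest; returns paths."""
    check_breakdown(result)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    path = out_dir / "base_case.tsv"
    results_table(result).to_csv(path, sep="\t", index=False, float_format="%.4f")
    written.append(path)

    from .config import model_config

    mc = model_config(cfg)
    for arm_result in (result.intervention, result.comparator):
        if arm_result.trace is None:
            continue
        path = out_dir / f"trace_{arm_result.arm}.tsv"
        arm_result.trace.to_frame(mc).to_csv(path, sep="\t", index=False, float_format="%.8f")
        written.append(path)

    for name, table in (extra_tables or {}).items():
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6f")
        written.append(path)

    manifest = RunManifest(
        config_hash=config_hash(cfg),
        seed=seed,
        package_version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        outputs=[str(p) for p in written],
    )
    manifest_path = out_dir / "manifest.json"
    manifest.write(manifest_path)
    written.append(manifest_path)
    return written
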