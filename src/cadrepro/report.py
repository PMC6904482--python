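"""Full-pipeline evaluation and report generation.

Produces, for one detection method on one paired dataset, the summary a
reader study would table: JAFROC figure of merit with a 95% interval,
PPA/CPPA mean +/- spread over the FP-budget operating points, the a/b/c/d
confusion grid per operating point, and the FROC curve. Reports are plain
dicts serialised as JSON (full precision) with a fixed key order, so a rerun
with the same inputs and seed is byte-identical; the human-readable table
prints at two decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .agreement import DEFAULT_FP_TARGETS, agreement_over_thresholds
from .annotations import Dataset, load_dataset
from .froc import fom_ci, froc_curve, match_dataset
from .matching import MatchConfig

__all__ = ["RunConfig", "evaluate_dataset", "format_table", "run_evaluation"]


@dataclass(frozen=True)
class RunConfig:
    """Evaluation settings for one run."""

    fp_targets: tuple[float, ...] = DEFAULT_FP_TARGETS
    iou_threshold: float = 0.5
    n_boot: int = 2000
    seed: int = 0
    method_name: str = "detector"
    froc_roles: str = "both"
    ci_method: str = "bootstrap"

    def __post_init__(self) -> None:
        if len(self.fp_targets) == 0:
            raise ValueError("fp_targets must be non-empty")
        if any(t < 0 for t in self.fp_targets):
            raise ValueError("fp_targets must be non-negative")
        if list(self.fp_targets) != sorted(self.fp_targets):
            raise ValueError("fp_targets must be sorted ascending")

    @property
    def match_config(self) -> MatchConfig:
        return MatchConfig(iou_threshold=self.iou_threshold)


def evaluate_dataset(dataset: Dataset, run: RunConfig = RunConfig()) -> dict:
    """Evaluate one dataset end to end and return the report dict."""
    config = run.match_config
    fom = fom_ci(
        dataset,
        n_boot=run.n_boot,
        seed=run.seed,
        config=config,
        method=run.ci_method,
    )
    agreement = agreement_over_thresholds(
        dataset, run.fp_targets, config, froc_roles=run.froc_roles
    )
    matches = match_dataset(dataset, config, roles=run.froc_roles)
    curve = froc_curve(list(matches.values()))
    return {
        "method": run.method_name,
        "n_pairs": len(dataset.pairs),
        "n_lesions": dataset.n_lesions,
        "config": {
            "fp_targets": list(run.fp_targets),
            "iou_threshold": run.iou_threshold,
            "n_boot": run.n_boot,
            "seed": run.seed,
            "froc_roles": run.froc_roles,
            "ci_method": run.ci_method,
            "std_convention": "population",
        },
        "fom": {
            "value": fom.fom,
            "ci_low": fom.ci_low,
            "ci_high": fom.ci_high,
            "method": fom.method,
        },
        "ppa": {"mean": agreement.ppa_mean, "std": agreement.ppa_std},
        "cppa": {"mean": agreement.cppa_mean, "std": agreement.cppa_std},
        "thresholds": [
            {
                "fp_target": r.fp_target,
                "tau": r.tau,
                "a": r.confusion.a,
                "b": r.confusion.b,
                "c": r.confusion.c,
                "d": r.confusion.d,
                "ppa": r.ppa,
                "cppa": r.cppa,
            }
            for r in agreement.per_threshold
        ],
        "froc": [
            {"tau": p.tau, "avg_fp": p.avg_fp, "sensitivity": p.sensitivity}
            for p in curve.points
        ],
    }


def format_table(report: dict) -> str:
    """Two-decimal human-readable summary of a report dict."""
    fom = report["fom"]
    lines = [
        f"Method: {report['method']}   "
        f"({report['n_pairs']} pairs, {report['n_lesions']} lesions)",
        f"FOM (95% CI): {fom['value']:.2f} ({fom['ci_low']:.2f}-{fom['ci_high']:.2f})",
        f"PPA (%):  {report['ppa']['mean']:.2f} ± {report['ppa']['std']:.2f}",
        f"CPPA (%): {report['cppa']['mean']:.2f} ± {report['cppa']['std']:.2f}",
        "",
        f"{'fp_target':>9}  {'tau':>8}  {'a':>4} {'b':>4} {'c':>4} {'d':>4}  "
        f"{'PPA':>7}  {'CPPA':>7}",
    ]
    for row in report["thresholds"]:
        lines.append(
            f"{row['fp_target']:>9.2f}  {row['tau']:>8.4f}  "
            f"{row['a']:>4d} {row['b']:>4d} {row['c']:>4d} {row['d']:>4d}  "
            f"{row['ppa']:>7.2f}  {row['cppa']:>7.2f}"
        )
    return "\n".join(lines)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")


def run_evaluation(
    gt_path,
    det_path,
    run: RunConfig = RunConfig(),
    out_dir=None,
) -> dict:
    """Load a dataset, evaluate, and optionally write report.json + froc.csv."""
    dataset = load_dataset(gt_path, det_path)
    report = evaluate_dataset(dataset, run)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json")
        curve_rows = report["froc"]
        lines = ["tau,avg_fp,sensitivity"]
        lines += [
            f"{r['tau']!r},{r['avg_fp']!r},{r['sensitivity']!r}" for r in curve_rows
        ]
        (out / "froc.csv").write_text("\n".join(lines) + "\n")
    return report
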