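"""End-to-end analysis: models -> references -> RQ -> statistics -> CS.

One call to :func:`run_analysis` reproduces the whole workflow for a fixed
removal level: enumerate the experimental and daughter models, run the
NormFinder removal loop and reference selection per model, normalize every
target gene in every model, test all sample pairs, and score coherence.
The run is deterministic given the inputs and configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .coherence import CoherenceReport, average_cs, build_report, comparison_value
from .models import ModelSpace, generate_models
from .normfinder import ReferenceAssignment, StabilityTable, assign_references
from .quantify import RQTable, compute_rq
from .stats import PairTestResult, run_tests
from .tables import ExpressionTable, RunConfig, validate_run


@dataclass(frozen=True)
class ResultBundle:
    """Everything a run produced, ready for export."""

    config: RunConfig
    space: ModelSpace
    stability: dict[int, list[StabilityTable]]  # model_id -> levels 0..r
    assignments: dict[int, ReferenceAssignment]
    rq: RQTable
    tests: dict[tuple[int, str], list[PairTestResult]]  # (model_id, target)
    reports: dict[str, CoherenceReport]
    average_cs: float


def run_analysis(ct: ExpressionTable, quant: ExpressionTable,
                 config: RunConfig) -> ResultBundle:
    ct, quant, config = validate_run(ct, quant, config)
    space = generate_models(ct.samples)

    stability: dict[int, list[StabilityTable]] = {}
    assignments: dict[int, ReferenceAssignment] = {}
    for model in space.models:
        final, levels = assign_references(
            quant, model, config.candidate_genes,
            remove_repetitions=config.remove_repetitions,
            select_best_remove=config.select_best_remove,
        )
        stability[model.model_id] = levels
        assignments[model.model_id] = final

    entries: dict[tuple[int, str], pd.Series] = {}
    tests: dict[tuple[int, str], list[PairTestResult]] = {}
    for model in space.models:
        assignment = assignments[model.model_id]
        # per-model cosmetic rescaling; models lacking the calibrator sample
        # stay unscaled (comparisons are rescaling-invariant anyway)
        calibrator = (config.calibrator
                      if config.calibrator in model.samples else None)
        for target in config.target_genes:
            rq = compute_rq(ct, model, target, assignment,
                            calibrator=calibrator)
            entries[(model.model_id, target)] = rq
            tests[(model.model_id, target)] = run_tests(
                rq, model, target, config.stat_method, alpha=config.alpha,
                welch=config.welch, log=config.log_rq,
            )
    rq_table = RQTable(entries, assignments)

    reports = {
        target: build_report(
            space, target,
            {mid: tests[(mid, target)] for mid in
             (m.model_id for m in space.models)},
            config.alpha, use_adjusted_p=config.use_adjusted_p,
        )
        for target in config.target_genes
    }
    avg = average_cs([reports[t].cs for t in config.target_genes])
    return ResultBundle(config, space, stability, assignments, rq_table,
                        tests, reports, avg)


# ---------------------------------------------------------------------------
# exports

_FLOAT = "%.6g"


def _fmt(x: float) -> str:
    return _FLOAT % x


def export_tables(bundle: ResultBundle, output_dir: str | Path) -> list[Path]:
    """Write stability.csv, rq.csv, stats.csv, coherence.csv and
    run_metadata.json; re-running on identical inputs is byte-identical."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    rows = []
    for mid in sorted(bundle.stability):
        model = bundle.space[mid]
        final = bundle.assignments[mid]
        for stab in bundle.stability[mid]:
            chosen = min(
                [(rho, 0, (g,)) for g, rho in stab.single_stability.items()]
                + [(rho, 1, tuple(sorted(p))) for p, rho in stab.pair_stability.items()]
            )
            rows.append({
                "model_id": mid,
                "model": "+".join(model.samples),
                "level": stab.removal_level,
                "pool": "+".join(stab.pool),
                "removed": "+".join(stab.removed_genes),
                "reference": "/".join(chosen[2]),
                "stability": _fmt(chosen[0]),
                "final_reference": final.label,
                "final_stability": _fmt(final.stability),
                "final_level": final.chosen_level,
            })
    path = out / "stability.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    written.append(path)

    rows = []
    for (mid, target), rq in sorted(bundle.rq.entries.items()):
        for (sample, rep), value in rq.items():
            rows.append({"model_id": mid, "target": target, "sample": sample,
                         "replicate": rep, "rq": _fmt(value),
                         "reference": bundle.assignments[mid].label})
    path = out / "rq.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    written.append(path)

    rows = []
    for (mid, target), results in sorted(bundle.tests.items()):
        for r in results:
            rows.append({
                "model_id": mid, "target": target,
                "sample_1": r.pair[0], "sample_2": r.pair[1],
                "raw_p": _fmt(r.raw_p), "adj_p": _fmt(r.adj_p),
                "median_1": _fmt(r.median_1), "median_2": _fmt(r.median_2),
                "comparison": comparison_value(r, bundle.config.alpha),
            })
    path = out / "stats.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    written.append(path)

    rows = []
    for target in bundle.config.target_genes:
        report = bundle.reports[target]
        for pair, partial in report.partial_cs.items():
            rows.append({"target": target, "sample_1": pair[0],
                         "sample_2": pair[1], "partial_cs": partial,
                         "cs": "%.2f" % report.cs})
    rows.append({"target": "AVERAGE", "sample_1": "", "sample_2": "",
                 "partial_cs": "", "cs": "%.2f" % bundle.average_cs})
    path = out / "coherence.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    written.append(path)

    meta = {
        "version": __version__,
        "config": {
            "candidate_genes": list(bundle.config.candidate_genes),
            "target_genes": list(bundle.config.target_genes),
            "remove_repetitions": bundle.config.remove_repetitions,
            "select_best_remove": bundle.config.select_best_remove,
            "alpha": bundle.config.alpha,
            "stat_method": bundle.config.stat_method,
            "use_adjusted_p": bundle.config.use_adjusted_p,
            "log_rq": bundle.config.log_rq,
            "welch": bundle.config.welch,
            "calibrator": bundle.config.calibrator,
        },
        "samples": list(bundle.space.universe),
        "n_models": len(bundle.space.models),
        "average_cs": round(bundle.average_cs, 6),
        "cs": {t: round(r.cs, 6) for t, r in bundle.reports.items()},
    }
    path = out / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written


def export_plots(bundle: ResultBundle, output_dir: str | Path) -> list[Path]:
    """One PNG per model: RQ box-plots per target x sample with red bars
    marking significant pairs (adjusted p < alpha)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    targets = bundle.config.target_genes
    written = []
    for model in bundle.space.models:
        mid = model.model_id
        fig, axes = plt.subplots(
            1, len(targets), figsize=(2.2 * len(targets) * max(1, model.size / 3), 3.2),
            squeeze=False, sharey=False,
        )
        for ax, target in zip(axes[0], targets):
            data = [bundle.rq.rq(mid, target).loc[s].to_numpy()
                    for s in model.samples]
            ax.boxplot(data, tick_labels=list(model.samples), whis=1.5)
            top = max(np.max(d) for d in data)
            step = 0.08 * max(top, 1e-12)
            height = top + step
            for r in bundle.tests[(mid, target)]:
                if r.adj_p < bundle.config.alpha:
                    i = model.samples.index(r.pair[0]) + 1
                    j = model.samples.index(r.pair[1]) + 1
                    ax.plot([i, j], [height, height], color="red", lw=1.2)
                    height += step
            ax.set_title(target, fontsize=9)
            ax.tick_params(axis="x", labelrotation=45, labelsize=7)
        fig.suptitle(
            f"Model {mid}: {'+'.join(model.samples)} "
            f"(ref {bundle.assignments[mid].label})", fontsize=9,
        )
        fig.tight_layout()
        path = out / f"model_{mid:03d}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
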