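"""End-to-end orchestration: expression -> rhythm -> gating ->
displacement -> triads, with audit tables and a machine-readable
summary.

Every stage writes its intermediate table, a filter funnel records the
gene counts surviving each filter, and ``summary.json`` aggregates the
direction x ETMR matrix, displacement-class counts and subgenome
proportions. Runs are deterministic given the same inputs and config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import displacement as disp
from . import triads as triads_mod
from .data import (
    StudyDesign,
    circular_distance_h,
    load_counts,
    load_triads,
)
from .expression import compute_cpm, differential_expression, filter_low_expression
from .gating import GatingAnalysis, filter_funnel, gating_summary
from .rhythm import ETMR_GROUPS

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Paths, thresholds and variant flags for one pipeline run.

    Thresholds default to the values used throughout the analysis:
    FDR < 0.05 and |logFC| > 0.5 for DEGs, rhythm p < 0.05 in a
    20-28 h period window, average CPM > 1 expression floor, minimum
    count 10 for the low-expression filter and +-0.5 on the mean
    normalized difference for direction calls.
    """

    counts: str | None = None
    design: str | None = None
    triads: str | None = None
    outdir: str = "results"
    fdr: float = 0.05
    lfc: float = 0.5
    rhythm_p: float = 0.05
    min_cpm: float = 1.0
    min_count: float = 10.0
    direction_threshold: float = 0.5
    period_min: float = 20.0
    period_max: float = 28.0
    fdr_scope: str = "per-timepoint"
    displacement_exclude: str = "gated-up-down"
    displacement_replicates: bool = True
    rhythm_method: str = "cosinor"
    seed: int = 0

    def __post_init__(self):
        for name in ("fdr", "rhythm_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not self.period_min < self.period_max:
            raise ValueError("period_min must be < period_max")
        if self.lfc < 0 or self.min_cpm < 0 or self.min_count < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def run_analysis(
    counts: pd.DataFrame,
    design: StudyDesign,
    triads: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Execute every stage on in-memory inputs; returns a dict of tables.

    Keys: cpm, retained_genes, deg_table, calls, delta_cpm, funnel,
    gating_summary, displacement, cohorts, cohort_summary, and (when a
    triad table is supplied) triad_contributions, triad_membership,
    subgenome_proportions.
    """
    cfg = config or PipelineConfig()
    period_range = (cfg.period_min, cfg.period_max)

    cpm_all = compute_cpm(counts)
    retained = filter_low_expression(counts, design, min_count=cfg.min_count)
    logger.info("expression filter: %d of %d genes retained", len(retained), len(counts))
    counts_f = counts.loc[retained]
    cpm = cpm_all.loc[retained]

    deg_table = differential_expression(
        counts_f, design, alpha=cfg.fdr, lfc=cfg.lfc, fdr_scope=cfg.fdr_scope
    )

    gate = GatingAnalysis(
        rhythm_p=cfg.rhythm_p,
        min_cpm=cfg.min_cpm,
        direction_threshold=cfg.direction_threshold,
        period_range=period_range,
        rhythm_method=cfg.rhythm_method,
    ).fit(cpm, design, deg_table)
    calls = gate.calls_

    displ = disp.DisplacementAnalysis().fit(cpm, design)
    cond_p = disp.condition_rhythm_pvalues(
        cpm,
        design,
        period_range=period_range,
        method=cfg.rhythm_method,
        use_replicates=cfg.displacement_replicates,
    )
    cohorts = disp.displacement_cohorts(
        displ.results_,
        calls["rhythm_p"],
        cond_p,
        calls,
        rhythm_p=cfg.rhythm_p,
        exclude=cfg.displacement_exclude,
    )

    out = {
        "cpm": cpm,
        "retained_genes": retained,
        "deg_table": deg_table,
        "calls": calls,
        "delta_cpm": gate.delta_cpm_,
        "funnel": filter_funnel(calls),
        "gating_summary": gating_summary(calls),
        "displacement": displ.results_,
        "adj_delta": displ.adj_delta_,
        "condition_rhythm_p": cond_p,
        "cohorts": cohorts,
        "cohort_summary": disp.cohort_summary_frame(cohorts),
    }

    if triads is not None and len(triads):
        out["triad_contributions"] = triads_mod.triad_contributions(
            gate.delta_cpm_, calls, triads
        )
        out["triad_membership"] = triads_mod.triad_etmr_membership(calls, triads)
        out["subgenome_proportions"] = triads_mod.subgenome_proportions(calls)
    return out


def summarize(results: dict) -> dict:
    """Machine-readable run summary, re-derivable from the written tables."""
    gsum = results["gating_summary"]
    summary = {
        "filter_funnel": {
            str(r.stage): int(r.n_genes) for r in results["funnel"].itertuples()
        },
        "direction_etmr_counts": {
            d: {g: int(gsum.at[d, g]) for g in gsum.columns} for d in gsum.index
        },
        "displacement_classes": {
            str(k): int(v)
            for k, v in results["displacement"]["ratio_class"]
            .value_counts()
            .items()
        },
        "displacement_cohorts": {
            name: {k: v for k, v in c.items() if k != "genes"}
            for name, c in results["cohorts"].items()
        },
    }
    if "subgenome_proportions" in results:
        sp = results["subgenome_proportions"]
        summary["subgenome_proportions"] = {
            grp: {
                col: (None if pd.isna(sp.at[grp, col]) else round(float(sp.at[grp, col]), 6))
                for col in sp.columns
                if col.startswith("prop_")
            }
            for grp in sp.index
        }
    return summary


def run_pipeline(config: PipelineConfig) -> Path:
    """Load inputs from the configured paths, run all stages, write outputs.

    Returns the output directory. A missing triad table only skips the
    triad stage (with a warning); other input errors abort.
    """
    if not config.counts or not config.design:
        raise ValueError("config must set counts and design paths")
    counts, design = load_counts(config.counts, config.design)

    triads = None
    if config.triads:
        if Path(config.triads).exists():
            triads = load_triads(config.triads)
        else:
            logger.warning("triad table %s not found; skipping triad stage", config.triads)

    results = run_analysis(counts, design, triads=triads, config=config)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    def _write(df: pd.DataFrame, name: str, index: bool = True) -> None:
        df.to_csv(outdir / name, sep="\t", float_format=_FLOAT_FMT, index=index)

    _write(results["deg_table"], "deg_table.tsv", index=False)
    _write(results["calls"], "gating_calls.tsv")
    _write(results["delta_cpm"], "delta_cpm.tsv")
    _write(results["funnel"], "filter_funnel.tsv", index=False)
    _write(results["gating_summary"], "gating_summary.tsv")
    _write(results["displacement"], "displacement.tsv")
    _write(results["adj_delta"], "adjusted_delta_cpm.tsv")
    _write(results["cohort_summary"], "displacement_cohorts.tsv", index=False)
    if "triad_contributions" in results:
        _write(results["triad_contributions"], "triad_contributions.tsv", index=False)
        _write(results["triad_membership"], "triad_membership.tsv")
        _write(results["subgenome_proportions"], "subgenome_proportions.tsv")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summarize(results), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


# ---------------------------------------------------------------------------
# Ground-truth validation (synthetic data)

_TRUTH_DIRECTION = {
    "gated_induction": "induction",
    "gated_reduction": "reduction",
    "stabilized": "displacement",
}


def validate_against_truth(results: dict, truth: pd.DataFrame) -> dict:
    """Recovery metrics of the pipeline against simulation ground truth.

    Returns per-direction precision and recall, conditional capture of
    stabilized genes given they pass all gating filters, circular ETMR
    error statistics for recovered gated genes, and the separation of
    displacement ratios between stabilized and gated genes.
    """
    calls = results["calls"]
    unknown = calls.index.difference(truth.index)
    if len(unknown):
        raise ValueError(f"genes missing from truth: {list(unknown[:5])}")

    expected = truth["response_class"].map(_TRUTH_DIRECTION)
    gated = calls[calls["gated"]]

    metrics: dict = {"direction": {}}
    for d in ("induction", "displacement", "reduction"):
        called = gated.index[gated["direction"] == d]
        truth_set = expected.index[expected == d]
        tp = len(set(called) & set(truth_set))
        metrics["direction"][d] = {
            "n_called": len(called),
            "n_true": len(truth_set),
            "precision": tp / len(called) if len(called) else np.nan,
            "recall": tp / len(truth_set) if len(truth_set) else np.nan,
        }

    # stabilized capture conditional on passing all three gating filters
    stab = truth.index[truth["response_class"] == "stabilized"]
    passing = calls.index[
        calls["passes_expression"] & calls["passes_deg"] & calls["passes_rhythm"]
    ]
    stab_pass = [g for g in stab if g in passing]
    if stab_pass:
        as_disp = (calls.loc[stab_pass, "direction"] == "displacement").mean()
    else:
        as_disp = np.nan
    metrics["stabilized_capture_given_pass"] = float(as_disp)

    gated_truth = truth.dropna(subset=["true_etmr"])
    recovered = gated.index.intersection(gated_truth.index)
    if len(recovered):
        err = circular_distance_h(
            calls.loc[recovered, "etmr_phase"].to_numpy(),
            gated_truth.loc[recovered, "true_etmr"].to_numpy(),
        )
        metrics["etmr"] = {
            "n_recovered": int(len(recovered)),
            "mae_h": float(np.mean(err)),
            "frac_within_4h": float(np.mean(err <= 4.0)),
        }
    else:
        metrics["etmr"] = {"n_recovered": 0, "mae_h": np.nan, "frac_within_4h": np.nan}

    ratios = results["displacement"]["ratio"]
    stab_r = ratios.reindex(stab).dropna()
    gated_classes = truth.index[
        truth["response_class"].isin(["gated_induction", "gated_reduction"])
    ]
    gate_r = ratios.reindex(gated_classes).dropna()
    metrics["displacement_separation"] = {
        "median_ratio_stabilized": float(stab_r.median()) if len(stab_r) else np.nan,
        "median_ratio_gated": float(gate_r.median()) if len(gate_r) else np.nan,
        "frac_stabilized_lt1": float((stab_r < 1).mean()) if len(stab_r) else np.nan,
    }

    # stabilized genes that enter a displacement cohort (rhythmic in both
    # condition CPM profiles, or rhythmic delta-CPM) with ratio < 1
    cohort_genes: set = set()
    for c in results.get("cohorts", {}).values():
        cohort_genes |= set(c["genes"])
    stab_in = ratios.reindex(pd.Index(sorted(cohort_genes & set(stab)))).dropna()
    metrics["displacement_separation"]["frac_stabilized_in_cohort_lt1"] = (
        float((stab_in < 1).mean()) if len(stab_in) else np.nan
    )
    metrics["displacement_separation"]["n_stabilized_in_cohort"] = int(len(stab_in))
    return metrics
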