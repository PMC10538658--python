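"""Cold-induced stabilization of transcript cycling (displacement ratio).

A transcript whose abundance is held for the 3 h cold treatment ends
the treatment where the control started it: its cold CPM at one
timepoint resembles the control CPM at the previous timepoint. The
adjusted delta-CPM captures this by pairing each control value with the
cold value one sampling interval later:

    Adj.dCPM(ZTx) = cold CPM(ZTx+4) - control CPM(ZTx),  x in 28..44

The displacement ratio is the mean |Adj.dCPM| over ZT28-44 divided by
the mean |dCPM| over the same five timepoints. Ratios below 1 indicate
the shifted pairing explains the cold response better than the
contemporaneous one — i.e. cycling was displaced — and below 0.5
markedly so.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import COLD, CONTROL, StudyDesign
from .gating import compute_delta_cpm, condition_means

logger = logging.getLogger(__name__)

RATIO_CLASSES = (">=1", "<1", "<0.5")


def compute_adjusted_delta(cpm: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Adjusted delta-CPM: cold mean at ZTx+4 minus control mean at ZTx.

    Defined for all timepoints except the last (ZT28-44 in the standard
    design); requires the cold mean at the final timepoint.
    """
    ctrl = condition_means(cpm, design, CONTROL)
    cold = condition_means(cpm, design, COLD)
    tps = design.timepoints
    step = int(design.sampling_interval)
    out = {}
    for zt in tps[:-1]:
        nxt = zt + step
        if nxt not in cold.columns:
            raise ValueError(f"cold mean at ZT{nxt} required for Adj.dCPM(ZT{zt})")
        out[zt] = cold[nxt] - ctrl[zt]
    return pd.DataFrame(out)


def displacement_ratio(delta_cpm: pd.DataFrame, adj_delta: pd.DataFrame) -> pd.DataFrame:
    """Per-gene displacement ratios and classes.

    Both means average absolute values over the adjusted timepoints
    (ZT28-44); genes with a zero mean delta-CPM get an undefined ratio
    and no class (logged).
    """
    zts = list(adj_delta.columns)
    mean_delta = delta_cpm[zts].abs().mean(axis=1)
    mean_adj = adj_delta.abs().mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean_adj / mean_delta
    ratio = ratio.where(mean_delta > 0)
    undefined = mean_delta <= 0
    if undefined.any():
        logger.warning("%d genes with zero mean delta-CPM: ratio undefined", int(undefined.sum()))
    cls = pd.Series(pd.NA, index=ratio.index, dtype="object")
    cls[ratio >= 1] = ">=1"
    cls[ratio < 1] = "<1"
    cls[ratio < 0.5] = "<0.5"
    return pd.DataFrame(
        {
            "mean_delta": mean_delta,
            "mean_adj_delta": mean_adj,
            "ratio": ratio,
            "ratio_class": cls,
        }
    )


class DisplacementAnalysis(BaseEstimator):
    """Compute adjusted delta-CPM and displacement ratios for all genes.

    Attributes
    ----------
    adj_delta_ : genes x ZT28-44 adjusted delta-CPM.
    results_ : per-gene mean_delta, mean_adj_delta, ratio, ratio_class.
    """

    def fit(self, cpm: pd.DataFrame, design: StudyDesign):
        delta = compute_delta_cpm(cpm, design)
        self.adj_delta_ = compute_adjusted_delta(cpm, design)
        self.results_ = displacement_ratio(delta, self.adj_delta_)
        return self


def displacement_cohorts(
    ratios: pd.DataFrame,
    delta_rhythm_p: pd.Series,
    condition_rhythm_p: pd.DataFrame | None,
    gating_calls: pd.DataFrame,
    rhythm_p: float = 0.05,
    exclude: str = "gated-up-down",
) -> dict:
    """Gene cohorts analysed for displacement, with ratio-class counts.

    Cohort (a): genes with a rhythmic delta-CPM profile, minus genes
    already called as circadian-gated inductions or reductions (to
    prevent double counting; ``exclude="all-gated"`` also removes gated
    displacements). Cohort (b): genes whose per-condition CPM profiles
    are rhythmic under both control and cold (columns ``control`` and
    ``cold`` of ``condition_rhythm_p``).

    Returns {cohort name: {"genes": Index, "n": int, "n_lt1": int,
    "n_lt05": int}}.
    """
    if exclude not in ("gated-up-down", "all-gated"):
        raise ValueError(f"unknown exclude mode {exclude!r}")
    gated = gating_calls[gating_calls["gated"]]
    if exclude == "gated-up-down":
        drop = set(gated.index[gated["direction"].isin(["induction", "reduction"])])
    else:
        drop = set(gated.index)

    cohorts = {}
    rhythmic_delta = delta_rhythm_p.index[delta_rhythm_p < rhythm_p]
    genes_a = ratios.index.intersection(rhythmic_delta.difference(pd.Index(drop)))
    cohorts["rhythmic_delta"] = _summarize(ratios.loc[genes_a])

    if condition_rhythm_p is not None:
        both = condition_rhythm_p.index[
            (condition_rhythm_p[CONTROL] < rhythm_p)
            & (condition_rhythm_p[COLD] < rhythm_p)
        ]
        genes_b = ratios.index.intersection(both)
        cohorts["rhythmic_both_conditions"] = _summarize(ratios.loc[genes_b])
    return cohorts


def _summarize(sub: pd.DataFrame) -> dict:
    defined = sub["ratio"].dropna()
    return {
        "genes": sub.index,
        "n": int(len(sub)),
        "n_lt1": int((defined < 1).sum()),
        "n_lt05": int((defined < 0.5).sum()),
    }


def cohort_summary_frame(cohorts: dict) -> pd.DataFrame:
    rows = [
        (name, c["n"], c["n_lt1"], c["n_lt05"]) for name, c in cohorts.items()
    ]
    return pd.DataFrame(rows, columns=["set", "n", "n_ratio_lt1", "n_ratio_lt0.5"])


def condition_rhythm_pvalues(
    cpm: pd.DataFrame,
    design: StudyDesign,
    period_range=(20.0, 28.0),
    method: str = "cosinor",
    use_replicates: bool = True,
) -> pd.DataFrame:
    """Per-condition rhythmicity p-values for every gene.

    With ``use_replicates`` (default) each replicate series is tested
    separately and p-values are Fisher-combined, mirroring a
    replicate-aware (meta3d-style) analysis; otherwise the replicate-
    mean profile is tested directly.
    """
    from scipy import stats as _stats

    from .rhythm import CosinorRhythmTest

    out = {}
    tps = design.timepoints
    for cond in design.conditions:
        if use_replicates:
            sam = design.samples
            reps = sorted(sam.loc[sam["condition"] == cond, "replicate"].unique())
            pvals = []
            for rep in reps:
                cols = [
                    sam.index[
                        (sam["condition"] == cond)
                        & (sam["timepoint_zt"] == zt)
                        & (sam["replicate"] == rep)
                    ][0]
                    for zt in tps
                ]
                est = CosinorRhythmTest(
                    timepoints=tps,
                    period_min=period_range[0],
                    period_max=period_range[1],
                    method=method,
                ).fit(cpm[cols].to_numpy())
                pvals.append(est.p_value_)
            pmat = np.clip(np.stack(pvals), 1e-12, 1.0)
            chi2 = -2.0 * np.log(pmat).sum(axis=0)
            out[cond] = _stats.chi2.sf(chi2, 2 * pmat.shape[0])
        else:
            means = condition_means(cpm, design, cond)
            est = CosinorRhythmTest(
                timepoints=tps,
                period_min=period_range[0],
                period_max=period_range[1],
                method=method,
            ).fit(means.to_numpy())
            out[cond] = est.p_value_
    return pd.DataFrame(out, index=cpm.index)
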