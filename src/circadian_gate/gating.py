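"""Cold-sensitivity profiles and circadian-gated response classification.

The per-gene cold-sensitivity signal is the delta-CPM profile: at each
timepoint, mean cold CPM minus mean control CPM (inductions positive).
Subtracting the contemporaneous control removes the underlying
circadian rhythm in abundance, so a circadian gate manifests as a ~24 h
oscillation in delta-CPM. Genes are called circadian-gated when they
(i) are expressed (average CPM > 1 in either condition), (ii) are
differentially expressed at least once across the time course and
(iii) have a rhythmic delta-CPM profile (p < 0.05 in the 20-28 h
window).

Direction is assigned on the mean-normalized scale, which removes
amplitude differences across the transcriptome: mean delta-mean-normCPM
> 0.5 is a gated induction, < -0.5 a gated reduction, and the interval
between marks displacement of transcript cycling. Each gated gene's
estimated time of maximum cold responsiveness (ETMR) is the phase of
the delta-CPM rhythm (trough phase, via the inverted profile, for
reductions), binned into 4 h groups. A final anomaly filter removes
genes in the edge bins whose |delta-CPM| is larger at the timepoint
opposite (+12 h) the estimated phase than at the phase itself.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import COLD, CONTROL, StudyDesign, nearest_timepoint
from .expression import compute_cpm
from .rhythm import CosinorRhythmTest, phase_to_etmr_group

logger = logging.getLogger(__name__)

DIRECTIONS = ("induction", "displacement", "reduction")
_EDGE_GROUPS = ("<4 h", ">20 h")


def condition_means(cpm: pd.DataFrame, design: StudyDesign, condition: str) -> pd.DataFrame:
    """Replicate-mean CPM per timepoint for one condition (genes x ZT)."""
    cols = {}
    for zt in design.timepoints:
        cols[zt] = cpm[design.sample_ids(condition, zt)].mean(axis=1)
    return pd.DataFrame(cols)


def compute_delta_cpm(cpm: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Delta-CPM profile per gene: mean cold - mean control at each ZT."""
    for zt in design.timepoints:
        for cond in (CONTROL, COLD):
            if not design.sample_ids(cond, zt):
                raise ValueError(f"no samples for {cond} at ZT{zt}")
    return condition_means(cpm, design, COLD) - condition_means(cpm, design, CONTROL)


def compute_mean_normalized(cpm: pd.DataFrame, design: StudyDesign):
    """Mean-normalized condition means and their difference.

    Each gene's per-condition, per-timepoint mean CPM is divided by the
    gene's grand mean over all condition x timepoint cells, so profiles
    are comparable across expression levels. Genes with a zero grand
    mean are dropped (logged).

    Returns (norm_control, norm_cold, delta_meannorm, mean_delta_meannorm).
    """
    ctrl = condition_means(cpm, design, CONTROL)
    cold = condition_means(cpm, design, COLD)
    grand = pd.concat([ctrl, cold], axis=1).mean(axis=1)
    zero = grand <= 0
    if zero.any():
        logger.warning("excluding %d genes with zero grand-mean CPM", int(zero.sum()))
        ctrl, cold, grand = ctrl[~zero], cold[~zero], grand[~zero]
    norm_ctrl = ctrl.div(grand, axis=0)
    norm_cold = cold.div(grand, axis=0)
    delta = norm_cold - norm_ctrl
    return norm_ctrl, norm_cold, delta, delta.mean(axis=1)


def classify_direction(mean_delta_meannorm: float, threshold: float = 0.5) -> str:
    """Directional class from the mean normalized cold-control difference.

    Values exactly at +-threshold fall to displacement (tie-break, logged).
    """
    v = float(mean_delta_meannorm)
    if not np.isfinite(v):
        raise ValueError("mean delta-mean-normCPM must be finite")
    if v == threshold or v == -threshold:
        logger.info("mean delta-mean-normCPM exactly at +-%.3g -> displacement", threshold)
        return "displacement"
    if v > threshold:
        return "induction"
    if v < -threshold:
        return "reduction"
    return "displacement"


class GatingAnalysis(BaseEstimator):
    """Classify circadian-gated cold responses from CPM and DEG tables.

    Parameters
    ----------
    rhythm_p : rhythmicity threshold on the delta-CPM profile.
    min_cpm : expression floor (average CPM in either condition).
    direction_threshold : +-cut on mean delta-mean-normCPM.
    period_range : permitted period window in hours.
    rhythm_method : backend passed to :class:`CosinorRhythmTest`.
    anomaly_filter : apply the opposing-timepoint filter to edge bins.

    Attributes
    ----------
    calls_ : per-gene DataFrame with filter provenance booleans,
        direction, ETMR phase/group, anomaly flag and the final
        ``gated`` call.
    """

    def __init__(
        self,
        rhythm_p: float = 0.05,
        min_cpm: float = 1.0,
        direction_threshold: float = 0.5,
        period_range: tuple = (20.0, 28.0),
        rhythm_method: str = "cosinor",
        anomaly_filter: bool = True,
    ):
        self.rhythm_p = rhythm_p
        self.min_cpm = min_cpm
        self.direction_threshold = direction_threshold
        self.period_range = period_range
        self.rhythm_method = rhythm_method
        self.anomaly_filter = anomaly_filter

    def fit(self, cpm: pd.DataFrame, design: StudyDesign, deg_table: pd.DataFrame):
        timepoints = design.timepoints
        delta = compute_delta_cpm(cpm, design)
        _, _, _, mean_dmn = compute_mean_normalized(cpm, design)
        mean_dmn = mean_dmn.reindex(delta.index)

        ctrl_avg = cpm[design.sample_ids(CONTROL)].mean(axis=1)
        cold_avg = cpm[design.sample_ids(COLD)].mean(axis=1)
        passes_expression = (ctrl_avg > self.min_cpm) | (cold_avg > self.min_cpm)

        deg_any = deg_table.groupby("gene_id")["is_deg"].any()
        passes_deg = deg_any.reindex(delta.index, fill_value=False).astype(bool)

        tester = CosinorRhythmTest(
            timepoints=timepoints,
            period_min=self.period_range[0],
            period_max=self.period_range[1],
            method=self.rhythm_method,
        ).fit(delta.to_numpy())
        rhythm_p = pd.Series(tester.p_value_, index=delta.index)
        phase = pd.Series(tester.phase_, index=delta.index)
        passes_rhythm = rhythm_p < self.rhythm_p

        direction = pd.Series(pd.NA, index=delta.index, dtype="object")
        etmr_phase = pd.Series(np.nan, index=delta.index)
        eligible = passes_expression & passes_deg & passes_rhythm
        direction.loc[eligible] = [
            classify_direction(v, self.direction_threshold)
            for v in mean_dmn.loc[eligible]
        ]

        etmr_phase.loc[eligible] = phase.loc[eligible]
        reductions = eligible & (direction == "reduction")
        if reductions.any():
            # trough phase: refit the inverted profile
            inv = CosinorRhythmTest(
                timepoints=timepoints,
                period_min=self.period_range[0],
                period_max=self.period_range[1],
                method=self.rhythm_method,
            ).fit(-delta.loc[reductions].to_numpy())
            etmr_phase.loc[reductions] = inv.phase_

        etmr_group = pd.Series(pd.NA, index=delta.index, dtype="object")
        etmr_group.loc[eligible] = [phase_to_etmr_group(p) for p in etmr_phase.loc[eligible]]

        anomaly = pd.Series(False, index=delta.index)
        if self.anomaly_filter:
            candidates = eligible & etmr_group.isin(_EDGE_GROUPS) & direction.isin(
                ["induction", "displacement"]
            )
            for gene in delta.index[candidates]:
                p = etmr_phase.loc[gene]
                zt_at = nearest_timepoint(p, timepoints)
                zt_opp = nearest_timepoint((p + 12.0) % 24.0, timepoints)
                if abs(delta.at[gene, zt_opp]) > abs(delta.at[gene, zt_at]):
                    anomaly.loc[gene] = True

        gated = eligible & ~anomaly
        self.calls_ = pd.DataFrame(
            {
                "passes_expression": passes_expression,
                "passes_deg": passes_deg,
                "passes_rhythm": passes_rhythm,
                "rhythm_p": rhythm_p,
                "mean_delta_meannorm": mean_dmn,
                "direction": direction,
                "etmr_phase": etmr_phase,
                "etmr_group": etmr_group,
                "anomaly_removed": anomaly,
                "gated": gated,
            }
        )
        self.calls_.index.name = "gene_id"
        self.delta_cpm_ = delta
        return self


def filter_gated_set(
    deg_table: pd.DataFrame,
    cpm: pd.DataFrame,
    design: StudyDesign,
    **params,
) -> pd.DataFrame:
    """Per-gene gating calls; thin wrapper over :class:`GatingAnalysis`."""
    return GatingAnalysis(**params).fit(cpm, design, deg_table).calls_


def assign_etmr(delta_profile, direction, timepoints=None, period_range=(20.0, 28.0)):
    """ETMR phase and 4 h group for one rhythmic delta-CPM profile.

    Inductions and displacements use the peak phase of the delta-CPM
    rhythm; reductions the phase of the inverted profile (the trough).
    """
    from .rhythm import detect_rhythm
    from .data import DEFAULT_TIMEPOINTS

    timepoints = DEFAULT_TIMEPOINTS if timepoints is None else timepoints
    profile = np.asarray(delta_profile, dtype=float)
    if direction == "reduction":
        profile = -profile
    res = detect_rhythm(profile, timepoints=timepoints, period_range=period_range)
    return res.phase, phase_to_etmr_group(res.phase)


def gating_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts of gated genes per direction x ETMR group."""
    from .rhythm import ETMR_GROUPS

    gated = calls[calls["gated"]]
    table = (
        gated.groupby(["direction", "etmr_group"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    return table.reindex(index=list(DIRECTIONS), columns=ETMR_GROUPS, fill_value=0)


def filter_funnel(calls: pd.DataFrame) -> pd.DataFrame:
    """Gene counts surviving each successive gating filter."""
    expr = calls["passes_expression"]
    deg = expr & calls["passes_deg"]
    rhy = deg & calls["passes_rhythm"]
    rows = [
        ("input", len(calls)),
        ("expressed", int(expr.sum())),
        ("deg_at_least_once", int(deg.sum())),
        ("rhythmic_delta_cpm", int(rhy.sum())),
        ("after_anomaly_filter", int(calls["gated"].sum())),
    ]
    return pd.DataFrame(rows, columns=["stage", "n_genes"])
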