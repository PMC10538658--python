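"""CPM normalization, low-expression filtering, per-timepoint DE calls.

Differential expression between cold-treated and control samples is
tested independently at each timepoint on log2-CPM with a moderated
two-sample t-statistic: gene-wise residual variances are shrunk toward
a global prior fitted across all genes and timepoints by empirical
Bayes (the scaled-F / inverse-chi-square hierarchical model familiar
from limma, re-derived here from the moments of log s^2). P-values are
BH-adjusted within each timepoint's contrast by default, and a gene is
called differentially expressed (DEG) when FDR < 0.05 and
|log2 fold change| > 0.5.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .data import COLD, CONTROL, StudyDesign

logger = logging.getLogger(__name__)


def compute_cpm(counts: pd.DataFrame, norm_factors=None) -> pd.DataFrame:
    """Counts per million: 1e6 * count / library size, per sample column.

    ``norm_factors`` optionally rescales each library size (a hook for
    composition normalization such as TMM); by default plain CPM is
    used. Column sums of the result equal 1e6 exactly when no factors
    are applied.
    """
    libsize = counts.sum(axis=0).astype(float)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise ValueError(f"zero library size for samples: {bad}")
    if norm_factors is not None:
        libsize = libsize * pd.Series(norm_factors).reindex(libsize.index)
    return counts.div(libsize, axis=1) * 1e6


def filter_low_expression(
    counts: pd.DataFrame, design: StudyDesign, min_count: float = 10.0
) -> pd.Index:
    """Genes passing the smallest-group-size expression filter.

    A gene is retained when its CPM exceeds ``k`` in at least ``n``
    samples, where ``k`` is ``min_count`` rescaled to the median
    library size (k = 1e6 * min_count / median libsize) and ``n`` is
    the smallest condition x timepoint group size.
    """
    libsize = counts.sum(axis=0).astype(float)
    k = 1e6 * min_count / float(np.median(libsize))
    n = design.n_replicates
    cpm = compute_cpm(counts)
    keep = (cpm > k).sum(axis=1) >= n
    return counts.index[keep]


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation


def _trigamma_inverse(x: float, tol: float = 1e-8, maxiter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(maxiter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior to observed gene-wise variances.

    Under the hierarchical model s^2 ~ s0^2 * F(df, d0), the moments of
    log s^2 identify (d0, s0^2): the excess variance of
    log s^2 - E[log chi^2_df/df] over trigamma(df/2) equals
    trigamma(d0/2). Returns (prior df d0, prior variance s0^2); d0 may
    be inf when gene-wise variances are consistent with a single value.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


class ModeratedTTest(BaseEstimator):
    """Per-timepoint moderated cold-vs-control comparison on log2-CPM.

    Parameters
    ----------
    alpha : FDR threshold for the DEG call (default 0.05).
    lfc : |log2 fold change| threshold for the DEG call (default 0.5).
    prior_count : pseudo-CPM added before the log2 transform.
    fdr_scope : ``"per-timepoint"`` (BH within each contrast, default)
        or ``"global"`` (one BH batch across all timepoints).
    moderate : disable to recover the ordinary pooled two-sample t-test
        (equivalently, infinite weight on the gene-wise variance).

    Attributes
    ----------
    table_ : long DataFrame (gene, zt, logfc, pvalue, fdr, is_deg).
    prior_df_, prior_var_ : fitted empirical-Bayes hyperparameters.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        lfc: float = 0.5,
        prior_count: float = 0.5,
        fdr_scope: str = "per-timepoint",
        moderate: bool = True,
    ):
        self.alpha = alpha
        self.lfc = lfc
        self.prior_count = prior_count
        self.fdr_scope = fdr_scope
        self.moderate = moderate

    def fit(self, counts: pd.DataFrame, design: StudyDesign):
        if self.fdr_scope not in ("per-timepoint", "global"):
            raise ValueError(f"unknown fdr_scope {self.fdr_scope!r}")
        cpm = compute_cpm(counts)
        logcpm = np.log2(cpm + self.prior_count)

        rows = []
        for zt in design.timepoints:
            cold = logcpm[design.sample_ids(COLD, zt)].to_numpy()
            ctrl = logcpm[design.sample_ids(CONTROL, zt)].to_numpy()
            n1, n2 = cold.shape[1], ctrl.shape[1]
            diff = cold.mean(axis=1) - ctrl.mean(axis=1)
            df = n1 + n2 - 2
            if df > 0:
                sse = ((cold - cold.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
                sse += ((ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
                s2 = sse / df
            else:
                s2 = np.full(len(diff), np.nan)
            rows.append((zt, diff, s2, df, 1.0 / n1 + 1.0 / n2))

        dfs = np.array([r[3] for r in rows], dtype=float)
        if (dfs == 0).any():
            logger.warning(
                "single-replicate cells at some timepoints; falling back to a "
                "variance pooled across timepoints"
            )
            pooled = np.nanmean(np.stack([r[2] for r in rows]), axis=0)
            df_fallback = float(dfs.sum()) if dfs.sum() > 0 else 1.0
            rows = [
                (zt, diff, pooled if df == 0 else s2, df_fallback if df == 0 else df, v)
                for (zt, diff, s2, df, v) in rows
            ]

        if self.moderate:
            all_s2 = np.concatenate([r[2] for r in rows])
            df_typical = float(np.median([r[3] for r in rows]))
            d0, s0_2 = fit_f_dist(all_s2[all_s2 > 0], df_typical)
        else:
            d0, s0_2 = 0.0, 0.0
        self.prior_df_ = d0
        self.prior_var_ = s0_2

        frames = []
        for zt, diff, s2, df, vfac in rows:
            if np.isinf(d0):
                s2_post = np.full_like(s2, s0_2)
                df_total = np.inf
            else:
                s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
                df_total = df + d0
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = diff / np.sqrt(s2_post * vfac)
            tstat = np.where(np.isfinite(tstat), tstat, 0.0)
            pval = (
                2.0 * stats.norm.sf(np.abs(tstat))
                if np.isinf(df_total)
                else 2.0 * stats.t.sf(np.abs(tstat), df_total)
            )
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": counts.index,
                        "zt": zt,
                        "logfc": diff,
                        "pvalue": pval,
                    }
                )
            )
        table = pd.concat(frames, ignore_index=True)

        if self.fdr_scope == "global":
            table["fdr"] = bh_adjust(table["pvalue"].to_numpy())
        else:
            table["fdr"] = table.groupby("zt")["pvalue"].transform(
                lambda p: bh_adjust(p.to_numpy())
            )
        table["is_deg"] = (table["fdr"] < self.alpha) & (
            table["logfc"].abs() > self.lfc
        )
        self.table_ = table
        return self


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    return multipletests(pvalues, method="fdr_bh")[1]


def differential_expression(
    counts: pd.DataFrame,
    design: StudyDesign,
    alpha: float = 0.05,
    lfc: float = 0.5,
    fdr_scope: str = "per-timepoint",
    moderate: bool = True,
) -> pd.DataFrame:
    """DEG table for cold vs control at each timepoint; see ModeratedTTest."""
    if design.n_replicates < 2:
        logger.warning("cells with a single replicate: pooled-variance fallback")
    est = ModeratedTTest(alpha=alpha, lfc=lfc, fdr_scope=fdr_scope, moderate=moderate)
    return est.fit(counts, design).table_


def degs_per_timepoint(deg_table: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint DEG counts and unique-to-one-timepoint fractions.

    Returns one row per ZT with n_up / n_down (DEGs with positive /
    negative logFC) and the fraction of each set that is differentially
    expressed at no other timepoint.
    """
    degs = deg_table[deg_table["is_deg"]]
    n_tp_per_gene = degs.groupby("gene_id")["zt"].nunique()
    out = []
    for zt, sub in degs.groupby("zt"):
        up = sub[sub["logfc"] > 0]["gene_id"]
        down = sub[sub["logfc"] < 0]["gene_id"]
        uniq_up = float((n_tp_per_gene.loc[up] == 1).mean()) if len(up) else np.nan
        uniq_down = float((n_tp_per_gene.loc[down] == 1).mean()) if len(down) else np.nan
        out.append((zt, len(up), len(down), uniq_up, uniq_down))
    return pd.DataFrame(
        out, columns=["zt", "n_up", "n_down", "frac_unique_up", "frac_unique_down"]
    ).set_index("zt")
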