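"""Subgenome and homoeolog-triad resolution of circadian-gated responses.

Hexaploid bread wheat carries three ancestral subgenomes (A, B, D);
corresponding gene copies form 1:1:1 triads. This module asks where
gated cold responses live: the subgenome composition of each ETMR
group, which triads enter a group (any gated member qualifies the
triad), and how the cold response of a triad distributes over its three
members.

A triad member's responsiveness at the group's time window is the mean
delta-CPM at the two sampled timepoints flanking the ETMR group
(ZT_lower and ZT_upper); the relative contribution of member x is its
share of the summed member responsiveness. Shares are only
interpretable as proportions when all members' values agree in sign;
mixed-sign triads are flagged and excluded from default summaries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import COLD, CONTROL, StudyDesign, subgenome_of
from .gating import condition_means
from .rhythm import ETMR_GROUPS, ETMR_GROUP_ENDPOINTS

logger = logging.getLogger(__name__)

_MEMBER_COLS = ("gene_A", "gene_B", "gene_D")
SUBGENOMES = ("A", "B", "D")


def delta_cpm_etmr(delta_profile: pd.Series, etmr_group: str) -> float:
    """Mean delta-CPM at the two sampled endpoints of an ETMR group.

    The "<4 h" group wraps circularly: its lower endpoint is ZT48, the
    subjective dawn of the next cycle (ZT24 was not sampled).
    """
    lo, hi = ETMR_GROUP_ENDPOINTS[etmr_group]
    return float((delta_profile[lo] + delta_profile[hi]) / 2.0)


def relative_contribution(values) -> tuple[tuple[float, float, float] | None, str]:
    """Share of each triad member in the summed responsiveness.

    Returns ``(shares, flag)`` where flag is ``"ok"``, ``"mixed-sign"``
    (shares computed on raw values but not interpretable as
    proportions) or ``"undefined"`` (zero sum; shares None).
    """
    v = np.asarray(values, dtype=float)
    total = v.sum()
    if total == 0 or not np.isfinite(total):
        return None, "undefined"
    signs = np.sign(v[v != 0])
    flag = "ok" if (signs >= 0).all() or (signs <= 0).all() else "mixed-sign"
    shares = tuple(float(x) for x in v / total)
    return shares, flag


def triad_contributions(
    delta_cpm: pd.DataFrame,
    calls: pd.DataFrame,
    triads: pd.DataFrame,
    directions=("induction", "displacement"),
) -> pd.DataFrame:
    """Per (triad, ETMR group) member responsiveness and ternary shares.

    A triad belongs to an ETMR group if any member is a gated call of
    an included direction in that group; all three members'
    responsiveness is then evaluated at that group's endpoints.
    ``n_groups_spanned`` counts the distinct groups a triad enters.
    """
    gated = calls[calls["gated"] & calls["direction"].isin(directions)]
    group_of = gated["etmr_group"]
    rows = []
    for _, tr in triads.iterrows():
        members = [tr[c] for c in _MEMBER_COLS]
        present = [g for g in members if g in delta_cpm.index]
        if len(present) < 3:
            continue
        groups = sorted(
            {group_of[g] for g in members if g in group_of.index},
            key=ETMR_GROUPS.index,
        )
        for grp in groups:
            vals = [delta_cpm_etmr(delta_cpm.loc[g], grp) for g in members]
            shares, flag = relative_contribution(vals)
            rows.append(
                {
                    "triad_id": tr["triad_id"],
                    "etmr_group": grp,
                    "delta_A": vals[0],
                    "delta_B": vals[1],
                    "delta_D": vals[2],
                    "cA": shares[0] if shares else np.nan,
                    "cB": shares[1] if shares else np.nan,
                    "cD": shares[2] if shares else np.nan,
                    "flag": flag,
                    "n_groups_spanned": len(groups),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "triad_id", "etmr_group", "delta_A", "delta_B", "delta_D",
            "cA", "cB", "cD", "flag", "n_groups_spanned",
        ],
    )


def dominance_category(shares, threshold: float = 0.5) -> str:
    """"A"/"B"/"D" when one member's share exceeds the dominance
    threshold, else "balanced"."""
    for sub, s in zip(SUBGENOMES, shares):
        if s > threshold:
            return sub
    return "balanced"


def subgenome_proportions(
    calls: pd.DataFrame, directions=("induction", "displacement")
) -> pd.DataFrame:
    """Per ETMR group: gated-gene counts and proportions by subgenome.

    Unplaced (U) and unparseable gene identifiers are excluded from the
    proportion denominators.
    """
    gated = calls[calls["gated"] & calls["direction"].isin(directions)].copy()
    gated["subgenome"] = [subgenome_of(g) for g in gated.index]
    gated = gated[gated["subgenome"].isin(SUBGENOMES)]
    counts = (
        gated.groupby(["etmr_group", "subgenome"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=ETMR_GROUPS, columns=list(SUBGENOMES), fill_value=0)
    )
    props = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0)
    props.columns = [f"prop_{c}" for c in props.columns]
    return pd.concat([counts, props], axis=1)


NIGHT_GROUPS = ("12-16 h", "16-20 h", ">20 h")
DAY_GROUPS = ("<4 h", "4-8 h", "8-12 h")


def night_day_proportion_gap(proportions: pd.DataFrame, subgenome: str = "D") -> float:
    """Pooled subjective-night minus subjective-day share of one subgenome.

    ``proportions`` is the output of :func:`subgenome_proportions`;
    counts are pooled over the three night (>= 12 h) and three day
    ETMR groups before taking shares.
    """
    night = proportions.loc[list(NIGHT_GROUPS), list(SUBGENOMES)].sum()
    day = proportions.loc[list(DAY_GROUPS), list(SUBGENOMES)].sum()
    return float(night[subgenome] / night.sum() - day[subgenome] / day.sum())


def triad_etmr_membership(calls: pd.DataFrame, triads: pd.DataFrame) -> pd.DataFrame:
    """Per ETMR group: triads with 1, 2 or 3 gated members."""
    gated = calls[calls["gated"]]
    gene_to_triad = {}
    for _, tr in triads.iterrows():
        for c in _MEMBER_COLS:
            gene_to_triad[tr[c]] = tr["triad_id"]
    rows = []
    for grp in ETMR_GROUPS:
        in_group = gated.index[gated["etmr_group"] == grp]
        per_triad: dict[str, int] = {}
        for g in in_group:
            tid = gene_to_triad.get(g)
            if tid is not None:
                per_triad[tid] = per_triad.get(tid, 0) + 1
        sizes = pd.Series(per_triad, dtype=int)
        rows.append(
            {
                "etmr_group": grp,
                "n_gated_genes": len(in_group),
                "n_triads": len(sizes),
                "n_with_1": int((sizes == 1).sum()),
                "n_with_2": int((sizes == 2).sum()),
                "n_with_3": int((sizes == 3).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("etmr_group")


def control_vs_cold_contribution(
    cpm: pd.DataFrame,
    design: StudyDesign,
    triads: pd.DataFrame,
    etmr_group: str,
) -> pd.DataFrame:
    """Paired member shares of total triad abundance, control vs cold.

    Shares are computed from mean CPM (not delta-CPM) at the group's
    two endpoint timepoints, separately per condition; a condition with
    zero triad total gets undefined shares.
    """
    lo, hi = ETMR_GROUP_ENDPOINTS[etmr_group]
    rows = []
    means = {
        cond: condition_means(cpm, design, cond) for cond in (CONTROL, COLD)
    }
    for _, tr in triads.iterrows():
        members = [tr[c] for c in _MEMBER_COLS]
        if any(g not in cpm.index for g in members):
            continue
        row = {"triad_id": tr["triad_id"], "etmr_group": etmr_group}
        for cond in (CONTROL, COLD):
            m = means[cond]
            vals = np.array([(m.at[g, lo] + m.at[g, hi]) / 2.0 for g in members])
            total = vals.sum()
            shares = vals / total if total > 0 else [np.nan] * 3
            for sub, s in zip(SUBGENOMES, shares):
                row[f"{cond}_c{sub}"] = float(s) if np.isfinite(s) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
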