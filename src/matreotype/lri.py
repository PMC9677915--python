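"""Ligand-receptor interaction scores and their group-wise contrasts.

The interaction score of a (ligand, receptor) pair in a sample is the
product of the two z-scaled expression values, score = R_i * L_i. Because
both factors are centered, co-depletion (both z negative) scores positive;
``truncate_negative`` zero-truncates z-values first for consumers who want
co-enrichment only. Pair scores aggregate to receptor classes or hallmark
pathways by the maximum over member pairs, and group contrasts reuse the
moderated two-group machinery of the differential-expression module.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .de import moderated_two_group
from .io import InputError
from .preprocess import ZScaledMatrix

logger = logging.getLogger("matreotype")


def interaction_scores(z: ZScaledMatrix, pairs: pd.DataFrame,
                       truncate_negative: bool = False) -> pd.DataFrame:
    """Per-pair, per-sample interaction scores (pairs x samples).

    Rows are indexed by (ligand, receptor); pairs with either gene absent
    from the matrix are dropped and reported.
    """
    have = set(z.z.index)
    usable = pairs[pairs["ligand"].isin(have) & pairs["receptor"].isin(have)]
    n_dropped = len(pairs) - len(usable)
    if n_dropped:
        logger.info("dropped %d pair(s) with a gene missing from the matrix",
                    n_dropped)
    if usable.empty:
        raise InputError("no ligand-receptor pair has both genes in the matrix")
    zmat = z.z
    if truncate_negative:
        zmat = zmat.clip(lower=0.0)
    lig = zmat.loc[usable["ligand"]].to_numpy(dtype=float)
    rec = zmat.loc[usable["receptor"]].to_numpy(dtype=float)
    idx = pd.MultiIndex.from_frame(usable[["ligand", "receptor"]])
    return pd.DataFrame(lig * rec, index=idx, columns=z.sample_ids)


def aggregate_interaction(scores: pd.DataFrame, pairs: pd.DataFrame,
                          grouping: str = "receptor_class") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate pair scores to a group x sample matrix by the maximum.

    ``grouping`` is ``receptor_class`` or ``pathway`` (pathways are the
    semicolon-delimited per-pair pathway lists; a pair can belong to
    several). Returns (aggregated matrix, membership table); groups with no
    scored member pair are dropped with a warning.
    """
    if grouping not in ("receptor_class", "pathway"):
        raise InputError(f"unknown grouping {grouping!r}")
    keyed = pairs.set_index(["ligand", "receptor"])
    members: dict[str, list[tuple[str, str]]] = {}
    for pair in scores.index:
        if pair not in keyed.index:
            continue
        row = keyed.loc[pair]
        if grouping == "receptor_class":
            groups = [row["receptor_class"]]
        else:
            groups = [p.strip() for p in str(row.get("pathways", "")).split(";")
                      if p.strip()]
        for g in groups:
            members.setdefault(g, []).append(pair)
    all_groups = (set(pairs["receptor_class"]) if grouping == "receptor_class"
                  else {p.strip() for ps in pairs.get("pathways", pd.Series(dtype=str))
                        for p in str(ps).split(";") if p.strip()})
    empty = sorted(all_groups - set(members))
    if empty:
        logger.warning("group(s) with no scored member pair dropped: %s",
                       empty[:10])
    if not members:
        raise InputError("no group covers any scored pair")
    agg = pd.DataFrame(
        {g: scores.loc[pair_list].max(axis=0)
         for g, pair_list in sorted(members.items())}
    ).T
    membership = pd.DataFrame(
        [(g, lig, rec) for g, pair_list in sorted(members.items())
         for lig, rec in pair_list],
        columns=["group", "ligand", "receptor"],
    )
    return agg, membership


def differential_interactions(aggregated: pd.DataFrame, groups: pd.Series,
                              group_a: str | None = None,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Moderated contrast of aggregated interaction scores between two
    matreotypes.

    logFC is mean(group_a) - mean(other); ``group_a`` defaults to the last
    sorted label (so with ECM-High/ECM-Low labels the contrast reads
    ECM-Low-referenced... pass group_a explicitly to fix the direction).
    """
    groups = groups.reindex(aggregated.columns)
    if groups.isna().any():
        raise InputError("matreotype labels missing for some samples")
    levels = sorted(groups.unique(), key=str)
    if len(levels) != 2:
        raise InputError(f"expected exactly 2 matreotype labels, got {levels}")
    if group_a is None:
        group_a = levels[-1]
    if group_a not in levels:
        raise InputError(f"group_a {group_a!r} not among {levels}")
    mask_a = (groups == group_a).to_numpy()
    mask_b = ~mask_a
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise InputError("each matreotype needs >= 2 samples")
    res = moderated_two_group(aggregated, mask_a, mask_b)
    adj = multipletests(res["p_value"].to_numpy(), method="fdr_bh")[1]
    out = res.assign(adj_p=adj, significant=adj < alpha)
    out.insert(0, "group", out.index)
    out.attrs["contrast"] = f"{group_a} vs rest"
    return out
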