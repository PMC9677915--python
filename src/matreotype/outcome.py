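"""Survival and association statistics for matreotypes and risk scores.

Kaplan-Meier estimation, the log-rank test, and Cox proportional hazards
(Efron tie handling, Wald intervals) are delegated to lifelines; this module
owns the data validation, reference-level handling, the Fisher enrichment
layout used to compare subtype labels, and rank-based group comparisons with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import InputError, NumericalError

logger = logging.getLogger("matreotype")

#: Ordinal coding of tumor stage for Cox covariates.
STAGE_CODES = {"I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass
class SurvFitResult:
    """Kaplan-Meier curves plus test / model summaries."""

    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    logrank_df: int | None = None
    cox_summary: pd.DataFrame | None = None
    model: str = ""


def _check_survival(surv: pd.DataFrame) -> pd.DataFrame:
    for col in ("time_months", "event"):
        if col not in surv.columns:
            raise InputError(f"survival table requires a {col!r} column")
    surv = surv.copy()
    surv["time_months"] = pd.to_numeric(surv["time_months"])
    surv["event"] = pd.to_numeric(surv["event"])
    if (surv["time_months"] <= 0).any():
        raise InputError("survival times must be positive")
    if not surv["event"].isin([0, 1]).all():
        raise InputError("event indicator must be 0 or 1")
    return surv


def km_logrank(surv: pd.DataFrame, groups: pd.Series) -> SurvFitResult:
    """Per-group Kaplan-Meier curves and the k-group log-rank test."""
    surv = _check_survival(surv)
    groups = groups.reindex(surv.index)
    if groups.isna().any():
        raise InputError("group labels missing for some survival samples")
    levels = sorted(groups.unique(), key=str)
    if len(levels) < 2:
        raise InputError("log-rank test needs >= 2 groups")
    curves = {}
    zero_event = []
    for lev in levels:
        mask = groups == lev
        kmf = KaplanMeierFitter()
        kmf.fit(surv.loc[mask, "time_months"], surv.loc[mask, "event"],
                label=str(lev))
        curves[str(lev)] = kmf.survival_function_.rename(
            columns={str(lev): "survival"})
        if surv.loc[mask, "event"].sum() == 0:
            zero_event.append(str(lev))
    if zero_event:
        logger.warning("group(s) with zero events: %s", zero_event)
    test_levels = [lev for lev in levels if str(lev) not in zero_event] \
        if len(levels) - len(zero_event) >= 2 else levels
    mask = groups.isin(test_levels)
    res = multivariate_logrank_test(
        surv.loc[mask.to_numpy(), "time_months"],
        groups[mask],
        surv.loc[mask.to_numpy(), "event"],
    )
    return SurvFitResult(
        km_curves=curves,
        logrank_chi2=float(res.test_statistic),
        logrank_p=float(res.p_value),
        logrank_df=len(test_levels) - 1,
        model=f"log-rank over groups {list(map(str, test_levels))}",
    )


def encode_stage(stage: pd.Series) -> pd.Series:
    """Ordinal-code tumor stage (I=1 ... IV=4); numeric input passes through."""
    def _one(v):
        if pd.isna(v):
            return np.nan
        s = str(v).strip().upper().removeprefix("STAGE").strip()
        if s in STAGE_CODES:
            return STAGE_CODES[s]
        try:
            return float(s)
        except ValueError:
            raise InputError(f"cannot encode stage value {v!r}") from None
    return stage.map(_one)


def cox_ph(surv: pd.DataFrame, groups_or_scores: pd.Series,
           covariates: pd.DataFrame | None = None,
           reference: str | None = None) -> SurvFitResult:
    """Cox proportional hazards with Efron tie handling.

    ``groups_or_scores`` may be categorical labels (dummy-coded against
    ``reference``, default the first sorted level) or a numeric score. Each
    term's coefficient, HR = exp(coef), 95% Wald CI and p are returned.
    """
    surv = _check_survival(surv)
    x = groups_or_scores.reindex(surv.index)
    if x.isna().any():
        raise InputError("group/score values missing for some survival samples")
    design = pd.DataFrame(index=surv.index)
    if pd.api.types.is_numeric_dtype(x):
        design[x.name or "score"] = x.astype(float)
    else:
        levels = sorted(x.unique(), key=str)
        ref = reference if reference is not None else levels[0]
        if ref not in levels:
            raise InputError(f"reference level {ref!r} not among {levels}")
        for lev in levels:
            if lev != ref:
                design[f"{x.name or 'group'}[{lev}]"] = (x == lev).astype(float)
    if covariates is not None:
        cov = covariates.reindex(surv.index)
        if cov.isna().any().any():
            raise InputError("covariates missing for some survival samples")
        for c in cov.columns:
            design[c] = pd.to_numeric(cov[c])
    n_events = int(surv["event"].sum())
    if n_events < 5 * design.shape[1]:
        logger.warning("only %d events for %d model terms", n_events,
                       design.shape[1])
    frame = pd.concat([surv[["time_months", "event"]], design], axis=1)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="time_months", event_col="event",
                    fit_options={"precision": 1e-12})
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise NumericalError(
            f"Cox model failed to converge ({exc}); consider stratification"
        ) from exc
    summ = cph.summary
    out = pd.DataFrame({
        "term": summ.index,
        "coef": summ["coef"],
        "hr": summ["exp(coef)"],
        "hr_ci_low": summ["exp(coef) lower 95%"],
        "hr_ci_high": summ["exp(coef) upper 95%"],
        "p_value": summ["p"],
    }).reset_index(drop=True)
    return SurvFitResult(cox_summary=out,
                         model=f"Cox PH (Efron ties), terms={list(design.columns)}")


def fisher_enrichment(labels_a: pd.Series, labels_b: pd.Series) -> pd.DataFrame:
    """Per-category Fisher exact tests of a binary grouping against categories.

    For each category of ``labels_b``, a 2x2 table (category vs rest) x
    (levels of ``labels_a``) is tested two-sided, summing hypergeometric
    probabilities at most that of the observed table (the R convention).
    ``labels_a`` must have exactly two levels.
    """
    common = labels_a.index.intersection(labels_b.index)
    a = labels_a.loc[common]
    b = labels_b.loc[common]
    levels_a = sorted(a.unique(), key=str)
    if len(levels_a) != 2:
        raise InputError("labels_a must have exactly 2 levels")
    rows = []
    for cat in sorted(b.unique(), key=str):
        in_cat = b == cat
        n11 = int(((a == levels_a[0]) & in_cat).sum())
        n12 = int(((a == levels_a[1]) & in_cat).sum())
        n21 = int(((a == levels_a[0]) & ~in_cat).sum())
        n22 = int(((a == levels_a[1]) & ~in_cat).sum())
        table = [[n11, n12], [n21, n22]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"category": str(cat), "n11": n11, "n12": n12,
                     "n21": n21, "n22": n22, "odds_ratio": odds, "p_value": p})
    return pd.DataFrame(rows).set_index("category")


def group_compare_bh(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per variable (row) with BH adjustment.

    Exact enumeration when both groups have <= 8 samples and no ties,
    otherwise the tie-corrected normal approximation. Constant variables
    get p = 1 and are flagged.
    """
    groups = groups.reindex(values.columns)
    if groups.isna().any():
        raise InputError("group labels missing for some samples")
    levels = sorted(groups.unique(), key=str)
    if len(levels) != 2:
        raise InputError("group_compare_bh requires exactly 2 groups")
    mask_a = (groups == levels[0]).to_numpy()
    mask_b = (groups == levels[1]).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise InputError("each group needs >= 2 samples")
    small = mask_a.sum() <= 8 and mask_b.sum() <= 8
    rows = []
    for var, row in values.iterrows():
        x = row.to_numpy(dtype=float)[mask_a]
        y = row.to_numpy(dtype=float)[mask_b]
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            rows.append({"variable": var, "U": np.nan, "p_value": 1.0,
                         "constant": True})
            continue
        has_ties = len(np.unique(np.r_[x, y])) < len(x) + len(y)
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append({"variable": var, "U": float(res.statistic),
                     "p_value": float(res.pvalue), "constant": False})
    out = pd.DataFrame(rows).set_index("variable")
    out["adj_p"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out
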