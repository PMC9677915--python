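"""Differential expression between tumor and non-tumor tissue, and discovery
of correlated core-matrisome gene clusters.

The two-group test uses an empirical-Bayes moderated t-statistic: gene-wise
residual variances are shrunk toward a pooled prior whose scale and degrees
of freedom are estimated by fitting a scaled F distribution to the observed
variance distribution (method of moments on log variances). The moderated t
is referred to a t distribution with augmented degrees of freedom, and
p-values are Benjamini-Hochberg adjusted across tested genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, InputError

logger = logging.getLogger("matreotype")


def _inv_trigamma(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y -= step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate prior df and prior scale of gene-wise variances.

    Fits s2 ~ s0^2 * F(df, d0) by matching the mean and variance of
    log(s2), the standard empirical-Bayes approach for microarray/RNA-seq
    linear models. Returns (d0, s0_squared); d0 may be inf when the observed
    variance of log(s2) is no larger than expected under equal variances.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _inv_trigamma(e_var)
    s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def moderated_two_group(values: pd.DataFrame, mask_a: np.ndarray,
                        mask_b: np.ndarray,
                        prior_df: float | None = None) -> pd.DataFrame:
    """Moderated two-group comparison of each row of ``values``.

    logFC is mean(group A) - mean(group B). ``prior_df`` overrides the
    estimated prior degrees of freedom (0 recovers the ordinary pooled-
    variance t-test; inf fully pools variances).
    """
    mask_a = np.asarray(mask_a, bool)
    mask_b = np.asarray(mask_b, bool)
    n1, n2 = int(mask_a.sum()), int(mask_b.sum())
    if n1 < 2 or n2 < 2:
        raise InputError("both groups need >= 2 samples")
    x = values.to_numpy(dtype=float)
    a, b = x[:, mask_a], x[:, mask_b]
    logfc = a.mean(axis=1) - b.mean(axis=1)
    df = n1 + n2 - 2
    ss = a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, df)
    else:
        d0 = float(prior_df)
        _, s0_sq = estimate_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(se > 0, p, 1.0)
    out = pd.DataFrame({
        "logFC": logfc, "t": t, "p_value": p, "s2_post": s2_post,
    }, index=values.index)
    out.attrs["prior_df"] = d0
    out.attrs["prior_s2"] = s0_sq
    return out


@dataclass
class DETable:
    """Per-gene two-group differential expression results."""

    table: pd.DataFrame  # gene, logFC, t, p_value, adj_p, significant, ...
    alpha: float
    prior_df: float


def differential_expression(expr: ExpressionMatrix, classes: pd.Series,
                            alpha: float = 0.05,
                            annotation: pd.DataFrame | None = None,
                            prior_df: float | None = None) -> DETable:
    """Tumor-vs-non-tumor moderated differential expression.

    ``classes`` maps sample id to "tumor"/"non_tumor". logFC is tumor minus
    non-tumor. Significance is BH-adjusted p < alpha (no fold-change floor).
    """
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    if expr.unit != "log2":
        raise InputError("differential expression expects log2 values")
    classes = classes.reindex(expr.sample_ids)
    if classes.isna().any():
        raise InputError("classes missing for some expression samples")
    mask_t = (classes == "tumor").to_numpy()
    mask_n = (classes == "non_tumor").to_numpy()
    if mask_t.sum() == 0 or mask_n.sum() == 0:
        raise InputError("both tumor and non_tumor samples are required")
    res = moderated_two_group(expr.data, mask_t, mask_n, prior_df=prior_df)
    adj = multipletests(res["p_value"].to_numpy(), method="fdr_bh")[1]
    table = res.assign(adj_p=adj, significant=adj < alpha)
    table.insert(0, "gene", table.index)
    if annotation is not None:
        table = table.join(annotation[["division", "category"]], how="left")
    return DETable(table, alpha, res.attrs["prior_df"])


@dataclass
class CorrelationClustering:
    """Spearman correlation structure of DE core-matrisome genes in tumors."""

    genes: list[str]
    rho: pd.DataFrame
    adj_p: pd.DataFrame
    labels: pd.Series           # gene -> cluster id (1..k)
    linkage: str = "average linkage on 1 - Spearman rho"


def correlation_clusters(expr: ExpressionMatrix, k: int = 4,
                         alpha: float = 0.05) -> CorrelationClustering:
    """Cluster genes by Spearman correlation across (tumor) samples.

    Pairwise Spearman rho with BH-adjusted two-sided p over the upper
    triangle; hierarchical clustering with average linkage on 1 - rho cut
    at ``k`` clusters. Constant genes are excluded with a warning.
    """
    if k < 2:
        raise InputError("k must be >= 2")
    if expr.n_samples < 5:
        raise InputError("correlation clustering needs >= 5 samples")
    data = expr.data
    sds = data.std(axis=1, ddof=1)
    if (sds == 0).any():
        dropped = list(data.index[sds == 0])
        logger.warning("excluding %d constant gene(s): %s", len(dropped),
                       dropped[:10])
        data = data.loc[sds > 0]
    genes = list(data.index)
    if len(genes) < k:
        raise InputError("fewer genes than clusters after filtering")
    n = data.shape[1]
    ranks = stats.rankdata(data.to_numpy(), axis=1)
    rho = np.corrcoef(ranks)
    np.fill_diagonal(rho, 1.0)
    # two-sided p via the t approximation on the correlation coefficient
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / np.clip(1.0 - rho ** 2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    iu = np.triu_indices(len(genes), k=1)
    adj_flat = multipletests(p[iu], method="fdr_bh")[1]
    adj = np.ones_like(p)
    adj[iu] = adj_flat
    adj.T[iu] = adj_flat
    np.fill_diagonal(adj, 0.0)
    dist = squareform(np.clip(1.0 - rho, 0.0, 2.0), checks=False)
    link = hierarchy.linkage(dist, method="average")
    labels = hierarchy.fcluster(link, t=min(k, len(genes)), criterion="maxclust")
    return CorrelationClustering(
        genes,
        pd.DataFrame(rho, index=genes, columns=genes),
        pd.DataFrame(adj, index=genes, columns=genes),
        pd.Series(labels, index=genes, name="cluster"),
    )
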