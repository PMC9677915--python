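"""Single-sample gene-set scores, the IPF fibrosis score, and per-cell
module scores.

The default set-scoring method is a rank-based running-sum enrichment
statistic computed independently per sample: genes are ranked by expression,
the running sum steps up by rank^0.25 (normalized) at set genes and down by
a constant at non-set genes, and the per-sample statistic is the area
between the two cumulative distributions, finally normalized by the range
across samples. It is a deterministic per-sample enrichment score; outputs
carry a method tag so downstream consumers know which scorer produced them.

The fibrosis score is the signed sum of z-scaled expression over a +/-1
weighted gene signature (genes up- or downregulated in idiopathic pulmonary
fibrosis lungs).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSetCollection, InputError
from .preprocess import ZScaledMatrix

logger = logging.getLogger("matreotype")

RANK_WEIGHT_EXPONENT = 0.25
MIN_SET_OVERLAP = 5


def _rank_enrichment_one_set(expr: np.ndarray, in_set: np.ndarray) -> np.ndarray:
    """Per-sample running-sum enrichment of one gene set.

    ``expr`` is genes x samples; ``in_set`` a boolean gene mask. For each
    sample, genes are ordered by decreasing expression; the statistic is the
    sum over positions of (weighted in-set CDF - out-of-set CDF)."""
    n_genes, n_samples = expr.shape
    ranks = stats.rankdata(expr, axis=0)  # 1 = lowest expression
    weights = ranks ** RANK_WEIGHT_EXPONENT
    scores = np.empty(n_samples)
    n_out = n_genes - int(in_set.sum())
    for j in range(n_samples):
        order = np.argsort(-expr[:, j], kind="mergesort")
        members = in_set[order]
        w = np.where(members, weights[order, j], 0.0)
        cdf_in = np.cumsum(w) / w.sum()
        cdf_out = np.cumsum(~members) / n_out
        scores[j] = np.sum(cdf_in - cdf_out)
    return scores


def gene_set_score(expr: ExpressionMatrix, sets: GeneSetCollection,
                   method: str = "rank_enrichment",
                   seed: int = 0) -> pd.DataFrame:
    """Per-sample scores for each gene set (sets x samples).

    Methods: ``rank_enrichment`` (default, see module docstring),
    ``weighted_z`` (mean per-gene z-scaled expression of the set), and
    ``module_score`` (expression-matched control genes, see
    :func:`module_score`). Sets sharing fewer than 5 genes with the matrix
    are skipped with a warning.
    """
    if method not in ("rank_enrichment", "weighted_z", "module_score"):
        raise InputError(f"unknown scoring method {method!r}")
    if len(sets) == 0:
        raise InputError("empty gene set collection")
    usable = {}
    for name, genes in sets.sets.items():
        present = [g for g in genes if g in expr.data.index]
        if len(present) < MIN_SET_OVERLAP:
            logger.warning("set %r shares %d < %d genes with the matrix; skipped",
                           name, len(present), MIN_SET_OVERLAP)
            continue
        usable[name] = present
    if not usable:
        raise InputError("no gene set shares enough genes with the matrix")
    x = expr.data.to_numpy(dtype=float)
    out = {}
    for name, genes in usable.items():
        mask = expr.data.index.isin(genes)
        if method == "rank_enrichment":
            raw = _rank_enrichment_one_set(x, mask)
            rng_ = raw.max() - raw.min()
            out[name] = raw / rng_ if rng_ > 0 else raw * 0.0
        elif method == "weighted_z":
            mu = x.mean(axis=1, keepdims=True)
            sd = x.std(axis=1, ddof=1, keepdims=True)
            z = np.divide(x - mu, sd, out=np.zeros_like(x), where=sd > 0)
            out[name] = z[mask].mean(axis=0)
        else:
            out[name] = module_score(expr, genes, seed=seed).to_numpy()
    result = pd.DataFrame(out, index=expr.sample_ids).T
    result.attrs["method"] = method
    return result


def fibrosis_score(z: ZScaledMatrix, signature: pd.DataFrame) -> pd.Series:
    """Signed sum of z-scaled expression over a +/-1-weighted signature.

    score(sample) = sum_i w_i * z_i over the signature genes present in the
    matrix; the number of missing signature genes is reported.
    """
    if not signature["weight"].isin([1, -1]).all():
        raise InputError("fibrosis weights must be +1 or -1")
    present = signature.index.intersection(z.z.index)
    if present.empty:
        raise InputError("no fibrosis signature gene present in the matrix")
    n_missing = len(signature) - len(present)
    if n_missing:
        logger.info("%d fibrosis signature gene(s) absent from the matrix",
                    n_missing)
    w = signature.loc[present, "weight"].to_numpy(dtype=float)
    scores = w @ z.z.loc[present].to_numpy(dtype=float)
    out = pd.Series(scores, index=z.sample_ids, name="fibrosis_score")
    out.attrs["n_missing_genes"] = int(n_missing)
    return out


def module_score(cells: ExpressionMatrix, gene_set, n_bins: int = 24,
                 n_control: int = 100, seed: int = 0) -> pd.Series:
    """Per-cell module score: mean set expression minus matched controls.

    Genes are binned into ``n_bins`` by average expression across cells; for
    each set gene, ``n_control`` control genes (capped at the bin size) are
    drawn from its bin, and the score is mean(set) - mean(pooled controls)
    per cell. Deterministic given the seed.
    """
    gene_set = [g for g in gene_set]
    missing = [g for g in gene_set if g not in cells.data.index]
    if missing:
        raise InputError(f"module gene(s) missing from matrix: {missing[:10]}")
    if len(gene_set) >= cells.n_genes:
        raise InputError("gene set is as large as the whole matrix")
    rng = np.random.default_rng(seed)
    avg = cells.data.mean(axis=1)
    order = avg.rank(method="first")
    bins = pd.cut(order, bins=n_bins, labels=False)
    control: set[str] = set()
    for g in gene_set:
        pool = bins.index[(bins == bins[g]) & (~bins.index.isin(gene_set))]
        take = min(n_control, len(pool))
        if take == 0:
            continue
        control.update(rng.choice(pool.to_numpy(), size=take, replace=False))
    if not control:
        raise InputError("no control genes available for the module score")
    set_mean = cells.data.loc[gene_set].mean(axis=0)
    ctrl_mean = cells.data.loc[sorted(control)].mean(axis=0)
    out = set_mean - ctrl_mean
    out.name = "module_score"
    return out
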