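"""Count filtering, TMM normalization, log2 transform, per-gene z-scaling.

TMM (trimmed mean of M-values) computes a per-sample scaling factor as the
precision-weighted mean of gene-wise log2 expression ratios (M-values)
against a reference sample, after trimming the most extreme 30% of M-values
and 5% of average-abundance (A) values. Factors are normalized to have unit
geometric mean and fold into effective library sizes; expression is then
reported as log2(CPM + 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, InputError

logger = logging.getLogger("matreotype")

TRIM_M = 0.3   # per-tail trim fraction on M-values
TRIM_A = 0.05  # per-tail trim fraction on A-values


@dataclass
class ZScaledMatrix:
    """Per-gene standardized expression, with the scaling model retained.

    ``mean``/``sd`` are the per-gene statistics of the scaling cohort so
    external samples can be projected onto the same scale. Genes with zero
    variance in the scaling cohort are excluded and listed in ``dropped``.
    """

    z: pd.DataFrame           # genes x samples
    mean: pd.Series
    sd: pd.Series
    dropped: list[str] = field(default_factory=list)
    provenance: str = ""

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.columns)

    def subset_genes(self, genes) -> "ZScaledMatrix":
        genes = [g for g in genes if g in self.z.index]
        return ZScaledMatrix(self.z.loc[genes], self.mean.loc[genes],
                             self.sd.loc[genes], list(self.dropped),
                             self.provenance)

    def subset_samples(self, samples) -> "ZScaledMatrix":
        return ZScaledMatrix(self.z[list(samples)], self.mean, self.sd,
                             list(self.dropped), self.provenance)


def filter_counts(counts: ExpressionMatrix, min_count: float = 10,
                  min_prop: float = 0.2) -> ExpressionMatrix:
    """Keep genes with count >= min_count in at least min_prop of samples."""
    if counts.unit != "counts":
        raise InputError("filtering expects a counts matrix")
    frac = (counts.data >= min_count).mean(axis=1)
    kept = counts.data.loc[frac >= min_prop]
    if kept.empty:
        raise InputError("all genes removed by the expression filter")
    logger.info("expression filter kept %d of %d genes", len(kept), counts.n_genes)
    return ExpressionMatrix(kept, "counts")


def _tmm_factor_pair(obs: np.ndarray, ref: np.ndarray,
                     lib_obs: float, lib_ref: float) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**)."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return 1.0
    p_obs = obs[pos] / lib_obs
    p_ref = ref[pos] / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic variance of M (delta method, binomial sampling)
    w = ((lib_obs - obs[pos]) / (lib_obs * obs[pos])
         + (lib_ref - ref[pos]) / (lib_ref * ref[pos]))
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0:
        return 1.0
    if np.allclose(m, m[0], atol=1e-10):
        # all ratios identical (e.g. a rescaled copy of the reference)
        return float(2.0 ** m[0])
    n = m.size
    lo_m = np.floor(n * TRIM_M) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * TRIM_A) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(counts: ExpressionMatrix) -> pd.Series:
    """Per-sample TMM normalization factors (unit geometric mean).

    The reference sample is the one whose 75th percentile of library-scaled
    counts is closest to the mean 75th percentile across samples.
    """
    x = counts.data.to_numpy(dtype=float)
    libs = x.sum(axis=0)
    if (libs == 0).any():
        bad = [counts.sample_ids[i] for i in np.flatnonzero(libs == 0)]
        raise InputError(f"sample(s) with zero total counts: {bad}")
    q75 = np.array([np.quantile(x[:, j] / libs[j], 0.75) for j in range(x.shape[1])])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array([
        _tmm_factor_pair(x[:, j], x[:, ref_idx], libs[j], libs[ref_idx])
        for j in range(x.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def tmm_normalize_log2(counts: ExpressionMatrix, min_count: float = 10,
                       min_prop: float = 0.2) -> ExpressionMatrix:
    """Filter, TMM-normalize and log2-transform a count matrix.

    Output values are log2(CPM + 0.5) where CPM uses effective library sizes
    (library size x TMM factor).
    """
    if counts.unit != "counts":
        raise InputError("tmm_normalize_log2 expects a counts matrix")
    if counts.n_samples < 2:
        raise InputError("TMM normalization requires at least 2 samples")
    kept = filter_counts(counts, min_count, min_prop)
    factors = tmm_factors(kept)
    libs = kept.data.sum(axis=0)
    eff = libs * factors
    logger.info("TMM factors: %s", np.round(factors.to_numpy(), 4).tolist()[:10])
    cpm = kept.data.div(eff, axis=1) * 1e6
    return ExpressionMatrix(np.log2(cpm + 0.5), "log2")


def zscale_genes(expr: ExpressionMatrix,
                 reference: ZScaledMatrix | None = None,
                 provenance: str = "") -> ZScaledMatrix:
    """Standardize each gene to mean 0, SD 1 (or project onto a reference).

    Without a reference, scaling uses this cohort's per-gene mean and sample
    SD; zero-variance genes are dropped with a warning. With a reference,
    the reference's stored mean/SD are applied to the shared genes.
    """
    if expr.unit != "log2":
        raise InputError("zscale_genes expects log2 expression")
    if reference is None:
        if expr.n_samples < 2:
            raise InputError("z-scaling needs >= 2 samples (or a reference model)")
        mean = expr.data.mean(axis=1)
        sd = expr.data.std(axis=1, ddof=1)
        keep = sd > 0
        dropped = list(expr.data.index[~keep])
        if dropped:
            logger.warning("dropped %d zero-variance gene(s): %s",
                           len(dropped), dropped[:10])
        z = expr.data.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
        return ZScaledMatrix(z, mean[keep], sd[keep], dropped, provenance)
    shared = [g for g in expr.gene_ids if g in reference.mean.index]
    if not shared:
        raise InputError("no genes shared with the reference scaling model")
    data = expr.data.loc[shared]
    z = data.sub(reference.mean.loc[shared], axis=0).div(
        reference.sd.loc[shared], axis=0)
    return ZScaledMatrix(z, reference.mean.loc[shared], reference.sd.loc[shared],
                         [], provenance or reference.provenance)


def write_zscale_model(zs: ZScaledMatrix, path) -> None:
    pd.DataFrame({"gene": zs.mean.index, "mean": zs.mean.to_numpy(),
                  "sd": zs.sd.to_numpy()}).to_csv(path, sep="\t", index=False)


def read_zscale_model(path) -> ZScaledMatrix:
    model = pd.read_csv(path, sep="\t").set_index("gene")
    empty = pd.DataFrame(index=model.index)
    return ZScaledMatrix(empty, model["mean"], model["sd"], [], str(path))
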