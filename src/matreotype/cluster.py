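"""Matreotype discovery by Monte-Carlo reference-based consensus clustering,
centroid construction and assignment, and canonical-subtype classification.

For each candidate cluster number K, K-means is run on many random sample
subsets; the consensus matrix records how often two samples co-cluster when
co-subsampled. Stability is summarized by the PAC score (proportion of
consensus entries in an ambiguous middle window). Significance comes from
Monte-Carlo reference datasets drawn multivariate-normal with the real
data's per-gene means and covariance eigenstructure, processed identically:
RCSI(K) = ln(mean null PAC) - ln(real PAC), and the Monte-Carlo p-value is
the fraction of null PACs at or below the real PAC (add-one corrected). The
chosen K maximizes RCSI among K with p < 0.05.

The RCSI here is the log-ratio form stated above; variants of this index
exist and consumers of the output metadata should rely on this definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .io import ExpressionMatrix, InputError
from .preprocess import ZScaledMatrix

logger = logging.getLogger("matreotype")

#: PAC values are floored at this value before taking logs in the RCSI.
PAC_FLOOR = 1e-4


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus: dict[int, np.ndarray]
    pac: dict[int, float]
    null_pac: dict[int, np.ndarray]
    rcsi: dict[int, float]
    mc_p: dict[int, float]
    chosen_k: int | None
    labels: pd.Series | None
    message: str = ""

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "K": self.k_range,
            "PAC": [self.pac[k] for k in self.k_range],
            "mean_null_PAC": [float(np.mean(self.null_pac[k]))
                              for k in self.k_range],
            "RCSI": [self.rcsi[k] for k in self.k_range],
            "MC_p": [self.mc_p[k] for k in self.k_range],
        })


@dataclass
class CentroidModel:
    """Per-label mean z-scaled expression centroids (genes x labels)."""

    centroids: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.centroids.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.centroids.index)


def pac_score(consensus: np.ndarray, window: tuple[float, float] = (0.1, 0.9)) -> float:
    """Fraction of upper-triangle consensus entries strictly inside ``window``."""
    lo, hi = window
    if lo >= hi:
        raise InputError("PAC window must satisfy lo < hi")
    consensus = np.asarray(consensus, dtype=float)
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = consensus[iu]
    if vals.size == 0:
        return 0.0
    return float(np.mean((vals > lo) & (vals < hi)))


def _consensus_matrix(x: np.ndarray, k: int, resamples: int,
                      subsample_frac: float, rng: np.random.Generator,
                      max_retries: int = 10) -> np.ndarray:
    """Subsampled K-means consensus matrix for one dataset at one K."""
    n = x.shape[0]
    m = max(int(np.floor(subsample_frac * n)), k)
    together = np.zeros((n, n))
    counted = np.zeros((n, n))
    for _ in range(resamples):
        for attempt in range(max_retries):
            idx = rng.choice(n, size=m, replace=False)
            sub = x[idx]
            if len(np.unique(sub, axis=0)) >= k:
                break
        else:
            raise InputError("could not draw a subsample with K distinct points")
        km = KMeans(n_clusters=k, n_init=1, max_iter=100,
                    random_state=int(rng.integers(2 ** 31 - 1)))
        labels = km.fit_predict(sub)
        counted[np.ix_(idx, idx)] += 1.0
        for c in range(k):
            members = idx[labels == c]
            together[np.ix_(members, members)] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(counted > 0, together / counted, 0.0)
    np.fill_diagonal(consensus, 1.0)
    return consensus


def _null_dataset(x: np.ndarray, rng: np.random.Generator,
                  eig: tuple[np.ndarray, np.ndarray] | None = None,
                  mode: str = "eigen") -> np.ndarray:
    """Reference dataset preserving per-gene means and covariance structure.

    ``mode="eigen"`` samples from N(mu, Sigma_hat) via the eigendecomposition
    of the gene covariance (rank-deficient Sigma is fine); ``mode="permute"``
    independently permutes each gene across samples.
    """
    if mode == "permute":
        out = x.copy()
        for j in range(out.shape[1]):
            out[:, j] = rng.permutation(out[:, j])
        return out
    mu = x.mean(axis=0)
    vals, vecs = eig
    z = rng.standard_normal((x.shape[0], len(vals)))
    return mu + z @ (vecs * np.sqrt(vals)).T


def consensus_cluster(z: ZScaledMatrix, k_range=range(2, 11),
                      resamples: int = 100, subsample_frac: float = 0.8,
                      mc_iters: int = 25, seed: int = 0,
                      null_mode: str = "eigen") -> ConsensusResult:
    """Monte-Carlo consensus clustering of samples on z-scaled genes."""
    k_range = sorted(k_range)
    x = z.z.to_numpy(dtype=float).T  # samples x genes
    n = x.shape[0]
    if n < max(k_range) * 3:
        raise InputError("need at least 3 samples per candidate cluster")
    rng = np.random.default_rng(seed)
    eig = None
    if null_mode == "eigen":
        cov = np.cov(x, rowvar=False)
        cov = np.atleast_2d(cov)
        vals, vecs = np.linalg.eigh(cov)
        keep = vals > max(vals.max(), 0) * 1e-12
        eig = (np.clip(vals[keep], 0, None), vecs[:, keep])

    consensus, pac = {}, {}
    for k in k_range:
        consensus[k] = _consensus_matrix(x, k, resamples, subsample_frac, rng)
        pac[k] = pac_score(consensus[k])

    null_pac: dict[int, list[float]] = {k: [] for k in k_range}
    for _ in range(mc_iters):
        xn = _null_dataset(x, rng, eig, null_mode)
        for k in k_range:
            cn = _consensus_matrix(xn, k, resamples, subsample_frac, rng)
            null_pac[k].append(pac_score(cn))

    rcsi, mc_p = {}, {}
    for k in k_range:
        nulls = np.array(null_pac[k])
        rcsi[k] = float(np.log(max(nulls.mean(), PAC_FLOOR))
                        - np.log(max(pac[k], PAC_FLOOR)))
        mc_p[k] = float((1 + np.sum(nulls <= pac[k])) / (mc_iters + 1))

    significant = [k for k in k_range if mc_p[k] < 0.05]
    if significant:
        chosen = max(significant, key=lambda k: rcsi[k])
        km = KMeans(n_clusters=chosen, n_init=25, random_state=seed)
        labels = pd.Series(km.fit_predict(x), index=z.sample_ids, name="cluster")
        message = f"chose K={chosen} by maximal RCSI among MC p < 0.05"
    else:
        chosen, labels = None, None
        message = "no significant structure (no K with Monte-Carlo p < 0.05)"
    logger.info(message)
    return ConsensusResult(list(k_range), consensus, pac,
                           {k: np.array(v) for k, v in null_pac.items()},
                           rcsi, mc_p, chosen, labels, message)


def build_centroids(z: ZScaledMatrix, labels: pd.Series) -> CentroidModel:
    """Per-label mean z-scaled expression over the clustering genes."""
    labels = labels.reindex(z.sample_ids)
    if labels.isna().any():
        raise InputError("labels missing for some samples")
    cent = {str(lab): z.z.loc[:, labels == lab].mean(axis=1)
            for lab in sorted(labels.unique(), key=str)}
    return CentroidModel(pd.DataFrame(cent))


def centroid_assign(z: ZScaledMatrix, model: CentroidModel) -> pd.Series:
    """Assign each sample to the nearest centroid (Euclidean distance).

    Distances are restricted to the model's genes; ties go to the first
    label in sorted order.
    """
    missing = [g for g in model.genes if g not in z.z.index]
    if missing:
        raise InputError(f"centroid gene(s) missing from matrix: {missing[:10]}")
    order = sorted(model.labels)
    zmat = z.z.loc[model.genes].to_numpy(dtype=float).T
    cents = model.centroids[order].to_numpy(dtype=float).T
    dist = cdist(zmat, cents, metric="euclidean")
    idx = np.argmin(dist, axis=1)  # argmin takes the first (sorted) label on ties
    return pd.Series([order[i] for i in idx], index=z.sample_ids,
                     name="matreotype")


def classify_canonical_subtype(expr: ExpressionMatrix,
                               centroids: pd.DataFrame) -> pd.DataFrame:
    """Nearest-centroid molecular subtyping by highest Pearson correlation.

    ``centroids`` is genes x subtypes (e.g. the published primitive /
    classical / secretory / basal centroids). Returns per-sample correlation
    with every centroid, the winning label, and a low-confidence flag when
    the best correlation is negative.
    """
    shared = [g for g in centroids.index if g in expr.data.index]
    if len(shared) < 10:
        raise InputError(
            f"only {len(shared)} genes shared with the centroid table (need >= 10)"
        )
    xs = expr.data.loc[shared].to_numpy(dtype=float)
    cs = centroids.loc[shared].to_numpy(dtype=float)
    xc = xs - xs.mean(axis=0)
    cc = cs - cs.mean(axis=0)
    denom = np.outer(np.linalg.norm(xc, axis=0), np.linalg.norm(cc, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc.T @ cc) / denom
    corr = np.nan_to_num(corr, nan=0.0)
    out = pd.DataFrame(corr, index=expr.sample_ids, columns=centroids.columns)
    best = out.idxmax(axis=1)
    best_r = out.max(axis=1)
    low = best_r < 0
    if low.any():
        logger.warning("%d sample(s) assigned with negative best correlation",
                       int(low.sum()))
    out["label"] = best
    out["best_r"] = best_r
    out["low_confidence"] = low
    return out
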