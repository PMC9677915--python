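"""Matrix risk signature: elastic-net gene selection, Firth-corrected
log-odds weights, per-sample risk scores, ROC validation, and minimal-
signature refinement.

The risk score of a sample is the weighted sum of its z-scaled expression
over the signature genes, score = sum_i z_i * beta_i, where beta_i is the
log odds ratio of gene i from a Firth-penalized logistic regression of
tumor vs non-tumor class. Firth's correction adds the Jeffreys prior
0.5*log det I(beta) to the log-likelihood, which keeps estimates finite
under complete separation and reduces small-sample bias.

Gene selection follows the glmnet convention: logistic loss (averaged over
samples) plus lambda * [alpha*||beta||_1 + (1-alpha)/2*||beta||_2^2], a
descending log-spaced lambda path from lambda_max (the smallest lambda
zeroing every coefficient), stratified cross-validated binomial deviance,
and the one-standard-error rule.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .io import InputError, NumericalError
from .preprocess import ZScaledMatrix

logger = logging.getLogger("matreotype")


@dataclass
class RiskSignature:
    """Ordered signature genes with log-odds-ratio weights."""

    genes: list[str]
    beta: np.ndarray
    intercept: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.genes) == 0:
            raise InputError("a risk signature needs at least one gene")
        if len(self.genes) != len(set(self.genes)):
            raise InputError("signature genes must be unique")
        if len(self.beta) != len(self.genes):
            raise InputError("beta length does not match gene list")
        if not np.isfinite(self.beta).all():
            raise NumericalError("signature weights must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.genes,
            "beta": self.beta,
            "odds_ratio": np.exp(self.beta),
        })


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def partition_cohort(metadata: pd.DataFrame, train_fraction: float = 0.8,
                     seed: int = 0) -> tuple[list[str], list[str]]:
    """Stratified (by tissue_class) train/test split; deterministic per seed."""
    if not 0 < train_fraction < 1:
        raise InputError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for _, group in metadata.groupby("tissue_class", sort=True):
        ids = np.array(group["sample_id"], dtype=object)
        if len(ids) < 5:
            raise InputError("each tissue class needs >= 5 samples to partition")
        perm = rng.permutation(len(ids))
        n_train = int(round(train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[perm[:n_train]])
        test.extend(ids[perm[n_train:]])
    return sorted(train), sorted(test)


def _binary_labels(classes: pd.Series, samples) -> np.ndarray:
    classes = classes.reindex(samples)
    if classes.isna().any():
        raise InputError("class labels missing for some samples")
    levels = sorted(classes.unique())
    if len(levels) != 2:
        raise InputError(f"expected exactly 2 classes, got {levels}")
    # tumor coded 1 when present, else the lexicographically later level
    positive = "tumor" if "tumor" in levels else levels[1]
    return (classes == positive).to_numpy().astype(float)


def _deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """Mean binomial deviance (-2 * mean log-likelihood)."""
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


_W_FLOOR = 1e-5  # floor on IRLS weights near fitted probabilities 0/1


@njit(cache=True)
def _enet_logistic_path(xt, y, lambdas, alpha, max_irls=30, max_sweeps=200,
                        cd_tol=1e-8, irls_tol=1e-7):  # pragma: no cover
    """Elastic-net logistic path by IRLS + active-set coordinate descent.

    Follows the glmnet scheme: descending lambda with warm starts; at each
    lambda, the logistic loss is locally approximated by a weighted least
    squares problem solved by cyclic coordinate descent over an active set,
    with Karush-Kuhn-Tucker checks over all features to grow the set.
    Returns (betas, intercepts) with one row per lambda."""
    p, n = xt.shape
    n_lam = lambdas.shape[0]
    betas = np.zeros((n_lam, p))
    b0s = np.zeros(n_lam)
    beta = np.zeros(p)
    ybar = y.mean()
    b0 = math.log(max(ybar, 1e-12) / max(1.0 - ybar, 1e-12))
    in_active = np.zeros(p, dtype=np.bool_)
    active = np.empty(p, dtype=np.int64)
    eta = np.empty(n)
    w = np.empty(n)
    r = np.empty(n)
    xwx = np.empty(p)
    for l_idx in range(n_lam):
        lam = lambdas[l_idx]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        for _ in range(max_irls):
            # quadratic approximation at the current linear predictor
            for i in range(n):
                e = b0
                for j in range(p):
                    if beta[j] != 0.0:
                        e += xt[j, i] * beta[j]
                if e > 30.0:
                    e = 30.0
                elif e < -30.0:
                    e = -30.0
                eta[i] = e
                mu = 1.0 / (1.0 + math.exp(-e))
                wi = mu * (1.0 - mu)
                if wi < _W_FLOOR:
                    wi = _W_FLOOR
                w[i] = wi
                r[i] = (y[i] - mu) / wi
            n_active = 0
            for j in range(p):
                in_active[j] = beta[j] != 0.0
                if in_active[j]:
                    active[n_active] = j
                    n_active += 1
                    s = 0.0
                    for i in range(n):
                        s += w[i] * xt[j, i] * xt[j, i]
                    xwx[j] = s / n
            max_change = 0.0
            for _ in range(100):  # active-set growth rounds
                # coordinate descent on the current active set
                for _ in range(max_sweeps):
                    max_delta = 0.0
                    for a in range(n_active):
                        j = active[a]
                        num = 0.0
                        for i in range(n):
                            num += w[i] * xt[j, i] * r[i]
                        num = num / n + xwx[j] * beta[j]
                        if num > l1:
                            bj = (num - l1) / (xwx[j] + l2)
                        elif num < -l1:
                            bj = (num + l1) / (xwx[j] + l2)
                        else:
                            bj = 0.0
                        delta = bj - beta[j]
                        if delta != 0.0:
                            for i in range(n):
                                r[i] -= delta * xt[j, i]
                            beta[j] = bj
                            step = abs(delta)
                            if step > max_delta:
                                max_delta = step
                            if step > max_change:
                                max_change = step
                    # unpenalized intercept
                    num = 0.0
                    den = 0.0
                    for i in range(n):
                        num += w[i] * r[i]
                        den += w[i]
                    d0 = num / den
                    if d0 != 0.0:
                        b0 += d0
                        for i in range(n):
                            r[i] -= d0
                        if abs(d0) > max_delta:
                            max_delta = abs(d0)
                        if abs(d0) > max_change:
                            max_change = abs(d0)
                    if max_delta < cd_tol:
                        break
                # KKT check over the excluded features
                n_viol = 0
                for j in range(p):
                    if not in_active[j]:
                        g = 0.0
                        for i in range(n):
                            g += w[i] * xt[j, i] * r[i]
                        if abs(g) / n > l1 + 1e-12:
                            s = 0.0
                            for i in range(n):
                                s += w[i] * xt[j, i] * xt[j, i]
                            xwx[j] = s / n
                            in_active[j] = True
                            active[n_active] = j
                            n_active += 1
                            n_viol += 1
                if n_viol == 0:
                    break
            if max_change < irls_tol:
                break
        betas[l_idx] = beta
        b0s[l_idx] = b0
    return betas, b0s


def _fit_path(x: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
              alpha_mix: float, seed: int = 0) -> list[tuple[np.ndarray, float]]:
    """Wrapper around the jitted path solver (seed kept for API symmetry)."""
    xt = np.ascontiguousarray(np.asarray(x, dtype=np.float64).T)
    y = np.asarray(y, dtype=np.float64)
    betas, b0s = _enet_logistic_path(xt, y, np.asarray(lambdas, float),
                                     float(alpha_mix))
    return [(betas[i], float(b0s[i])) for i in range(len(lambdas))]


def elastic_net_select(z: ZScaledMatrix, classes: pd.Series,
                       alpha_mix: float = 0.5, folds: int = 10,
                       seed: int = 0, n_lambda: int = 100,
                       lambda_min_ratio: float = 1e-4,
                       cv_metric: str = "deviance") -> dict:
    """Select signature genes by cross-validated elastic-net logistic path.

    ``cv_metric`` is "deviance" (binomial deviance, the glmnet default) or
    "class" (misclassification error rate). Returns a dict with selected
    genes at the 1-SE lambda (falling back to lambda_min with a warning when
    the 1-SE model is empty), both lambdas, and the CV error curve.
    """
    if not 0 < alpha_mix <= 1:
        raise InputError("alpha_mix must be in (0, 1]")
    if cv_metric not in ("deviance", "class"):
        raise InputError(f"unknown cv_metric {cv_metric!r}")
    x = z.z.to_numpy(dtype=float).T  # samples x genes
    y = _binary_labels(classes, z.sample_ids)
    n = len(y)
    if n < folds:
        raise InputError("fewer samples than CV folds")
    lam_max = np.max(np.abs(x.T @ (y - y.mean()))) / (n * alpha_mix)
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, n_lambda))
    for f, (tr, va) in enumerate(cv.split(x, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            raise InputError("a CV fold lost one of the classes")
        path = _fit_path(x[tr], y[tr], lambdas, alpha_mix, seed)
        for j, (coef, icpt) in enumerate(path):
            eta = x[va] @ coef + icpt
            if cv_metric == "class":
                dev[f, j] = float(np.mean((eta > 0) != (y[va] > 0.5)))
            else:
                dev[f, j] = _deviance(y[va], eta)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / math.sqrt(folds)
    j_min = int(np.argmin(mean_dev))
    threshold = mean_dev[j_min] + se_dev[j_min]
    j_1se = int(np.flatnonzero(mean_dev <= threshold)[0])  # largest lambda
    full_path = _fit_path(x, y, lambdas, alpha_mix, seed)
    genes = np.array(z.gene_ids, dtype=object)

    def _nonzero(j: int) -> list[str]:
        return list(genes[np.abs(full_path[j][0]) > 1e-10])

    selected = _nonzero(j_1se)
    chosen = "lambda_1se"
    if not selected:
        logger.warning("no gene selected at lambda_1se; falling back to lambda_min")
        selected = _nonzero(j_min)
        chosen = "lambda_min"
    return {
        "selected_genes": selected,
        "lambda_min": float(lambdas[j_min]),
        "lambda_1se": float(lambdas[j_1se]),
        "chosen": chosen,
        "lambdas": lambdas,
        "cv_deviance": mean_dev,
        "cv_se": se_dev,
    }


def _firth_fit(x: np.ndarray, y: np.ndarray, tol: float = 1e-8,
               max_iter: int = 200) -> np.ndarray:
    """Jeffreys-prior-penalized logistic fit (design x includes intercept)."""
    n, p = x.shape
    beta = np.zeros(p)

    def penalized_loglik(b: np.ndarray) -> float:
        eta = x @ b
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        info = x.T @ (x * w[:, None])
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return -np.inf
        return ll + 0.5 * logdet

    ll_old = penalized_loglik(beta)
    for _ in range(max_iter):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        info = x.T @ (x * w[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"singular information matrix: {exc}") from exc
        # hat diagonal of the weighted design
        h = np.einsum("ij,jk,ik->i", x, info_inv, x) * w
        score = x.T @ (y - mu + h * (0.5 - mu))
        if np.linalg.norm(score) < tol:
            return beta
        step = info_inv @ score
        for _ in range(40):
            ll_new = penalized_loglik(beta + step)
            if ll_new >= ll_old - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        ll_old = penalized_loglik(beta)
    eta = x @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = x.T @ (x * w[:, None])
    h = np.einsum("ij,jk,ik->i", x, np.linalg.inv(info), x) * w
    score = x.T @ (y - mu + h * (0.5 - mu))
    if np.linalg.norm(score) < 1e-4:  # slow but acceptable convergence
        return beta
    raise NumericalError(
        f"Firth logistic regression did not converge in {max_iter} iterations "
        f"(score norm {np.linalg.norm(score):.2e})"
    )


def firth_log_odds(z: ZScaledMatrix, classes: pd.Series,
                   mode: str = "joint",
                   covariates: pd.DataFrame | None = None) -> RiskSignature:
    """Firth-corrected log odds ratios for the signature genes.

    ``mode="joint"`` (default) fits one multivariable model over all genes;
    ``mode="per_gene"`` fits each gene alone with an intercept. Optional
    numeric ``covariates`` (samples x terms) are appended unpenalized into
    the joint design; their coefficients are recorded in provenance but are
    not part of the signature.
    """
    if mode not in ("joint", "per_gene"):
        raise InputError(f"unknown mode {mode!r}")
    y = _binary_labels(classes, z.sample_ids)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise InputError("both classes need >= 2 samples")
    genes = z.gene_ids
    zmat = z.z.to_numpy(dtype=float).T  # samples x genes
    if mode == "per_gene":
        betas = []
        for j in range(zmat.shape[1]):
            design = np.column_stack([np.ones(len(y)), zmat[:, j]])
            betas.append(_firth_fit(design, y)[1])
        return RiskSignature(genes, np.array(betas),
                             provenance={"mode": "per_gene"})
    cols = [np.ones(len(y)), zmat]
    names = ["(intercept)"] + list(genes)
    if covariates is not None:
        cov = covariates.reindex(z.sample_ids)
        if cov.isna().any().any():
            raise InputError("covariates missing for some samples")
        cols.append(cov.to_numpy(dtype=float))
        names += list(cov.columns)
    design = np.column_stack(cols)
    beta_full = _firth_fit(design, y)
    beta_genes = beta_full[1:1 + len(genes)]
    prov = {"mode": "joint", "intercept": float(beta_full[0])}
    if covariates is not None:
        prov["covariate_beta"] = dict(
            zip(covariates.columns, beta_full[1 + len(genes):]))
    return RiskSignature(list(genes), beta_genes, float(beta_full[0]), prov)


def matrix_risk_score(z: ZScaledMatrix, signature: RiskSignature) -> pd.Series:
    """Per-sample risk score: sum over signature genes of z_i * beta_i."""
    missing = [g for g in signature.genes if g not in z.z.index]
    if missing:
        raise InputError(f"signature gene(s) missing from matrix: {missing}")
    zmat = z.z.loc[signature.genes].to_numpy(dtype=float)
    scores = signature.beta @ zmat
    return pd.Series(scores, index=z.sample_ids, name="matrix_risk_score")


def roc_auc(scores: pd.Series, classes: pd.Series) -> RocCurve:
    """ROC curve and AUC of scores against binary class labels.

    The AUC is the rank statistic (probability a positive outranks a
    negative, ties counted half), identical to the trapezoidal integral of
    the empirical ROC curve.
    """
    y = _binary_labels(classes, scores.index)
    s = scores.to_numpy(dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("both classes must be present for ROC analysis")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(1 - y_sorted)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    return RocCurve(thresholds, fpr, tpr, float(auc))


def _cv_auc(zmat: np.ndarray, y: np.ndarray, cols: list[int],
            folds: int, seed: int) -> float:
    """Stratified-CV AUC of a Firth refit on a gene subset."""
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for tr, va in cv.split(zmat, y):
        design = np.column_stack([np.ones(len(tr)), zmat[np.ix_(tr, cols)]])
        beta = _firth_fit(design, y[tr])
        scores[va] = zmat[np.ix_(va, cols)] @ beta[1:]
    ranks = stats.rankdata(scores)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def refine_minimal_signature(z: ZScaledMatrix, signature: RiskSignature,
                             classes: pd.Series, max_size: int,
                             folds: int = 5, seed: int = 0,
                             exhaustive_limit: int = 100_000) -> pd.DataFrame:
    """Rank small gene subsets of the signature by cross-validated AUC.

    Exhaustive over all subsets of size <= max_size when their number is
    within ``exhaustive_limit``; otherwise greedy forward selection. Ties
    are broken by smaller subset, then lexicographic gene order.
    """
    if max_size < 1:
        raise InputError("max_size must be >= 1")
    if max_size > len(signature.genes):
        raise InputError("max_size exceeds the signature size")
    y = _binary_labels(classes, z.sample_ids)
    genes = sorted(signature.genes)
    zmat = z.z.loc[genes].to_numpy(dtype=float).T
    n_subsets = sum(math.comb(len(genes), k) for k in range(1, max_size + 1))
    rows = []
    if n_subsets <= exhaustive_limit:
        for k in range(1, max_size + 1):
            for combo in itertools.combinations(range(len(genes)), k):
                auc = _cv_auc(zmat, y, list(combo), folds, seed)
                rows.append({"genes": tuple(genes[i] for i in combo),
                             "size": k, "cv_auc": auc})
    else:
        chosen: list[int] = []
        remaining = list(range(len(genes)))
        for _ in range(max_size):
            best = None
            for cand in remaining:
                auc = _cv_auc(zmat, y, chosen + [cand], folds, seed)
                key = (-auc, genes[cand])
                if best is None or key < best[0]:
                    best = (key, cand, auc)
            chosen.append(best[1])
            remaining.remove(best[1])
            rows.append({"genes": tuple(genes[i] for i in sorted(chosen)),
                         "size": len(chosen), "cv_auc": best[2]})
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["cv_auc", "size", "genes"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return table
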