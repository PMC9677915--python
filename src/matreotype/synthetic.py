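"""Synthetic bulk-RNAseq cohorts with the structure the analysis assumes.

The generator emulates a tumor/non-tumor contrast in a squamous-carcinoma-like
cohort: negative-binomial counts around a block-correlated latent log2
expression profile, a planted set of differentially expressed "matrisome"
signature genes (half up-, half down-regulated in tumors), two tumor
subtypes differing in an ECM program block with a planted survival hazard
ratio, and a premalignant cohort whose progressive lesions drift toward the
tumor profile along a chosen subset of signature genes.

Defaults mirror the cohort scale of the analysis this package implements:
~240 tumors against a small non-tumor arm, ~2000 genes of which a minority
are matrisomal, a 1-SD differential-expression effect, a hazard ratio near 2
for the ECM-enriched subtype, and ~20% censoring.

One root seed spawns independent substreams per stage (latent expression,
counts, survival, censoring, premalignant draw) so adding a stage never
perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, InputError

# substream indices off the root SeedSequence
_STREAM_LATENT, _STREAM_COUNTS, _STREAM_SURVIVAL, _STREAM_CENSOR, _STREAM_PREMAL = range(5)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``block_spec`` lists (cluster size, within-block correlation rho) for
    correlated gene blocks laid out from the start of the gene list; the
    first block doubles as the ECM program that separates the two tumor
    subtypes. ``effect_size_sd_units`` is the tumor-vs-non-tumor mean shift
    of each planted signature gene, in units of the latent log2 SD.
    """

    n_tumor: int = 240
    n_non_tumor: int = 40
    n_genes_total: int = 2000
    n_matrisome: int = 300
    n_signature: int = 20
    block_spec: tuple[tuple[int, float], ...] = ((30, 0.7), (25, 0.6), (20, 0.5))
    effect_size_sd_units: float = 1.0
    matreotype_fraction: float = 0.6
    planted_log_hr: float = math.log(2.0)
    ecm_program_shift: float = 1.0
    baseline_hazard: float = math.log(2.0) / 30.0  # per month; median ~30 months
    censor_rate: float = 0.2
    horizon_months: float = 120.0
    nb_dispersion: float = 0.1
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    latent_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_non_tumor", "n_genes_total", "n_matrisome",
                     "n_signature"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if not 0 < self.matreotype_fraction < 1:
            raise InputError("matreotype_fraction must be in (0, 1)")
        for size, rho in self.block_spec:
            if size <= 0:
                raise InputError("block sizes must be positive")
            if not 0 <= rho < 1:
                raise InputError("block correlations must lie in [0, 1)")
        if sum(size for size, _ in self.block_spec) > self.n_matrisome:
            raise InputError("block_spec exceeds the number of matrisome genes")
        if self.n_signature > self.n_matrisome:
            raise InputError("n_signature exceeds n_matrisome")
        if self.n_matrisome > self.n_genes_total:
            raise InputError("n_matrisome exceeds n_genes_total")
        if not 0 <= self.censor_rate < 1:
            raise InputError("censor_rate must be in [0, 1)")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise InputError("library_size_range must be positive and ordered")
        if self.nb_dispersion < 0:
            raise InputError("nb_dispersion must be non-negative")


def gene_table(config: SyntheticConfig) -> pd.DataFrame:
    """Deterministic per-gene truth table: names, roles, blocks, effect signs.

    Gene names are ``G0001``... with role aliases (``SIG_UP_01`` etc.)
    recorded alongside. Signature genes are placed outside the correlated
    blocks so the planted differential effect and the block structure can be
    checked independently; the first block is the ECM program.
    """
    n = config.n_genes_total
    names = [f"G{i + 1:04d}" for i in range(n)]
    table = pd.DataFrame({
        "gene": names,
        "is_matrisome": [i < config.n_matrisome for i in range(n)],
        "block": -1,
        "block_rho": 0.0,
        "is_ecm_program": False,
        "is_signature": False,
        "effect_sign": 0,
        "alias": "",
    }).set_index("gene", drop=False)
    pos = 0
    for b, (size, rho) in enumerate(config.block_spec):
        table.iloc[pos:pos + size, table.columns.get_loc("block")] = b
        table.iloc[pos:pos + size, table.columns.get_loc("block_rho")] = rho
        if b == 0:
            table.iloc[pos:pos + size, table.columns.get_loc("is_ecm_program")] = True
        pos += size
    n_up = config.n_signature - config.n_signature // 2
    sig_rows = range(pos, pos + config.n_signature)
    if pos + config.n_signature > config.n_matrisome:
        raise InputError("not enough matrisome genes outside blocks for the signature")
    for j, row in enumerate(sig_rows):
        sign = 1 if j < n_up else -1
        table.iloc[row, table.columns.get_loc("is_signature")] = True
        table.iloc[row, table.columns.get_loc("effect_sign")] = sign
        tag = "SIG_UP" if sign > 0 else "SIG_DN"
        k = j + 1 if sign > 0 else j - n_up + 1
        table.iloc[row, table.columns.get_loc("alias")] = f"{tag}_{k:02d}"
    return table


def _latent_matrix(config: SyntheticConfig, genes: pd.DataFrame,
                   base_means: np.ndarray, n_samples: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw latent log2 expression (genes x samples) with block correlation.

    Equicorrelated blocks are sampled as sqrt(rho)*shared + sqrt(1-rho)*own,
    which realizes the exchangeable correlation matrix without a Cholesky
    factorization (and is positive definite for all rho in [0, 1))."""
    n_genes = len(genes)
    noise = rng.standard_normal((n_genes, n_samples))
    blocks = genes["block"].to_numpy()
    rhos = genes["block_rho"].to_numpy()
    for b in np.unique(blocks[blocks >= 0]):
        members = np.flatnonzero(blocks == b)
        rho = rhos[members[0]]
        shared = rng.standard_normal(n_samples)
        noise[members] = (math.sqrt(rho) * shared
                          + math.sqrt(1.0 - rho) * noise[members])
    return base_means[:, None] + config.latent_sd * noise


def _counts_from_latent(latent: np.ndarray, config: SyntheticConfig,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Negative-binomial counts (mean mu, variance mu + phi*mu^2) per sample."""
    rel = np.exp2(latent)
    rel /= rel.sum(axis=0, keepdims=True)
    lo, hi = config.library_size_range
    libs = rng.uniform(lo, hi, size=latent.shape[1])
    mu = rel * libs[None, :]
    phi = config.nb_dispersion
    if phi == 0:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        counts = rng.poisson(lam)
    return counts.astype(np.int64), libs


def generate_bulk_cohort(config: SyntheticConfig) -> dict:
    """Generate a tumor/non-tumor cohort with survival and a truth record.

    Returns a dict with keys ``expression`` (counts ExpressionMatrix),
    ``metadata`` (sample table incl. tissue_class), ``survival`` (tumor
    samples: time_months, event), ``truth_genes`` and ``truth_samples``.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(5)
    genes = gene_table(config)
    n_total = config.n_tumor + config.n_non_tumor
    sample_ids = [f"T{i + 1:04d}" for i in range(config.n_tumor)] + \
                 [f"N{i + 1:04d}" for i in range(config.n_non_tumor)]
    is_tumor = np.array([True] * config.n_tumor + [False] * config.n_non_tumor)

    rng_latent = np.random.default_rng(streams[_STREAM_LATENT])
    base_means = rng_latent.uniform(3.0, 10.0, size=len(genes))
    latent = _latent_matrix(config, genes, base_means, n_total, rng_latent)

    # planted tumor-vs-non-tumor effect on signature genes
    eff = config.effect_size_sd_units * config.latent_sd
    signs = genes["effect_sign"].to_numpy()
    latent[:, is_tumor] += (signs * eff)[:, None]

    # ECM-High subtype: first ceil(fraction * n_tumor) tumors, extra shift on
    # the ECM program block
    n_high = int(round(config.matreotype_fraction * config.n_tumor))
    n_high = min(max(n_high, 1), config.n_tumor - 1)
    matreotype = np.array(
        ["ECM-High"] * n_high + ["ECM-Low"] * (config.n_tumor - n_high)
        + ["Non-Tumor"] * config.n_non_tumor
    )
    program = genes["is_ecm_program"].to_numpy()
    high_mask = matreotype == "ECM-High"
    latent[np.ix_(program, high_mask)] += config.ecm_program_shift * config.latent_sd

    rng_counts = np.random.default_rng(streams[_STREAM_COUNTS])
    counts, libs = _counts_from_latent(latent, config, rng_counts)
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=genes.index, columns=sample_ids), "counts"
    )

    # exponential survival for tumors; hazard multiplied for ECM-High
    rng_surv = np.random.default_rng(streams[_STREAM_SURVIVAL])
    rng_cens = np.random.default_rng(streams[_STREAM_CENSOR])
    hazards = config.baseline_hazard * np.where(
        high_mask[is_tumor], math.exp(config.planted_log_hr), 1.0
    )
    t_event = rng_surv.exponential(1.0 / hazards)
    if config.censor_rate > 0:
        c_rate = hazards * config.censor_rate / (1.0 - config.censor_rate)
        t_cens = rng_cens.exponential(1.0 / c_rate)
    else:
        t_cens = np.full_like(t_event, np.inf)
    t_cens = np.minimum(t_cens, config.horizon_months)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    metadata = pd.DataFrame({
        "sample_id": sample_ids,
        "tissue_class": np.where(is_tumor, "tumor", "non_tumor"),
        "cohort": "synthetic",
    }).set_index("sample_id", drop=False)
    survival = pd.DataFrame({
        "sample_id": np.array(sample_ids)[is_tumor],
        "time_months": time,
        "event": event,
    }).set_index("sample_id", drop=False)
    truth_samples = pd.DataFrame({
        "sample_id": sample_ids,
        "matreotype": matreotype,
        "library_size": libs,
        "latent_risk": latent[genes["is_signature"].to_numpy()].mean(axis=0),
    }).set_index("sample_id", drop=False)
    return {
        "expression": expr,
        "metadata": metadata,
        "survival": survival,
        "truth_genes": genes,
        "truth_samples": truth_samples,
        "latent": pd.DataFrame(latent, index=genes.index, columns=sample_ids),
        "config": config,
    }


def generate_premalignant_cohort(config: SyntheticConfig, risk_genes,
                                 shift_fraction: float = 0.5,
                                 n_per_group: int = 30) -> dict:
    """Generate progressive/regressive premalignant lesions.

    All lesions share the non-tumor baseline profile; in progressive lesions
    each gene of ``risk_genes`` is shifted toward the tumor profile by
    ``shift_fraction`` of the planted tumor effect (genes without a planted
    effect are shifted upward by the same amount, so arbitrary risk gene
    lists remain usable).
    """
    risk_genes = list(risk_genes)
    if not risk_genes:
        raise InputError("risk_genes must be non-empty")
    genes = gene_table(config)
    unknown = [g for g in risk_genes if g not in genes.index]
    if unknown:
        raise InputError(f"risk gene(s) not in generated genes: {unknown[:10]}")

    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(5)
    rng_latent = np.random.default_rng(streams[_STREAM_LATENT])
    base_means = rng_latent.uniform(3.0, 10.0, size=len(genes))

    rng = np.random.default_rng(streams[_STREAM_PREMAL])
    n_total = 2 * n_per_group
    latent = _latent_matrix(config, genes, base_means, n_total, rng)
    labels = np.array(["progressive"] * n_per_group + ["regressive"] * n_per_group)
    eff = config.effect_size_sd_units * config.latent_sd
    signs = genes["effect_sign"].to_numpy().astype(float)
    shift = np.where(signs == 0, 1.0, signs) * eff * shift_fraction
    rows = genes.index.get_indexer(risk_genes)
    prog = labels == "progressive"
    latent[np.ix_(rows, prog)] += shift[rows][:, None]

    counts, libs = _counts_from_latent(latent, config, rng)
    sample_ids = [f"CIS{i + 1:03d}" for i in range(n_total)]
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=genes.index, columns=sample_ids), "counts"
    )
    truth = pd.DataFrame({
        "sample_id": sample_ids,
        "label": labels,
        "library_size": libs,
    }).set_index("sample_id", drop=False)
    return {"expression": expr, "labels": truth, "risk_genes": risk_genes,
            "shift_fraction": shift_fraction, "config": config}


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of ``config`` with a different root seed."""
    return replace(config, seed=seed)
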