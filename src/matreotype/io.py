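"""Readers and writers for the tabular formats used throughout the package.

All tables are UTF-8, tab-separated text. Gene identifiers are HGNC-style
symbols, uppercased and whitespace-trimmed on load; no identifier mapping is
performed. Expression matrices are genes x samples with a header row of
sample ids and the gene symbol in the first column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("matreotype")

CORE_CATEGORIES = frozenset({"collagens", "proteoglycans", "ECM_glycoproteins"})
ASSOCIATED_CATEGORIES = frozenset(
    {"ECM_affiliated", "ECM_regulators", "secreted_factors"}
)

#: Strings accepted as missing values in metadata tables (never in expression).
NA_STRINGS = ("", "NA")


class InputError(Exception):
    """Malformed or inconsistent input (CLI exit code 2)."""


class NumericalError(Exception):
    """A numerical procedure failed to converge or produced no result (exit 3)."""


@dataclass
class ExpressionMatrix:
    """A dense gene-by-sample expression matrix with a unit tag.

    ``unit`` is ``"counts"`` for raw (non-negative) count data and ``"log2"``
    for normalized log2-scale values.
    """

    data: pd.DataFrame  # genes x samples
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "log2"):
            raise InputError(f"unknown expression unit {self.unit!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene identifiers: {dups[:10]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample identifiers: {dups[:10]}")
        if self.data.isna().any().any():
            raise InputError("expression matrix contains missing values")
        if self.unit == "counts" and (self.data.to_numpy() < 0).any():
            raise InputError("count matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[genes], self.unit)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)], self.unit)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), with optional per-set descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise InputError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, genes) -> "GeneSetCollection":
        """Intersect every set with ``genes``; empty intersections are flagged."""
        universe = set(genes)
        kept, dropped = {}, []
        for name, members in self.sets.items():
            inter = [g for g in members if g in universe]
            if inter:
                kept[name] = inter
            else:
                dropped.append(name)
        if dropped:
            logger.warning(
                "%d gene set(s) had no genes in the matrix and were dropped: %s",
                len(dropped), dropped[:10],
            )
        return GeneSetCollection(kept, dict(self.descriptions))


def _normalize_symbols(values: pd.Index | pd.Series) -> pd.Index:
    return pd.Index([str(v).strip().upper() for v in values])


def read_expression_matrix(path, unit: str) -> ExpressionMatrix:
    """Read a genes x samples TSV into a validated :class:`ExpressionMatrix`.

    Duplicate gene symbols are collapsed by keeping the row with the highest
    mean expression (logged). Missing or non-numeric cells are an error
    naming the offending cell.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_cols = [c.strip() for c in header[1:]]
    if not sample_cols:
        raise InputError(f"{path}: missing header row of sample ids")
    seen: set[str] = set()
    dups = [c for c in sample_cols if c in seen or seen.add(c)]
    if dups:
        raise InputError(f"{path}: duplicate sample id(s) {sorted(set(dups))}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.columns.str.match(r"^Unnamed").all():
        raise InputError(f"{path}: missing header row of sample ids")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise InputError(
            f"{path}: non-numeric cell {raw.iat[gi, si]!r} at "
            f"gene {raw.index[gi]!r}, sample {raw.columns[si]!r}"
        )
    numeric.index = _normalize_symbols(numeric.index)
    if numeric.index.duplicated().any():
        dup_genes = numeric.index[numeric.index.duplicated()].unique()
        means = numeric.mean(axis=1)
        keep = np.ones(len(numeric), dtype=bool)
        for g in dup_genes:
            rows = np.flatnonzero(numeric.index == g)
            best = rows[np.argmax(means.iloc[rows].to_numpy())]
            keep[rows] = False
            keep[best] = True
        logger.info(
            "collapsed %d duplicate gene symbol(s) keeping the highest-mean row: %s",
            len(dup_genes), list(dup_genes[:10]),
        )
        numeric = numeric.loc[keep]
    return ExpressionMatrix(numeric, unit)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")


def read_sample_metadata(path, expression_samples=None) -> pd.DataFrame:
    """Read clinical metadata; ``tissue_class`` is required for every sample.

    When ``expression_samples`` is given, unmatched expression samples are
    reported with a warning and the returned frame is ordered to match.
    """
    meta = pd.read_csv(
        path, sep="\t", dtype=str, na_values=list(NA_STRINGS), keep_default_na=False
    )
    if "sample_id" not in meta.columns or "tissue_class" not in meta.columns:
        raise InputError(f"{path}: metadata requires sample_id and tissue_class columns")
    meta["sample_id"] = meta["sample_id"].astype(str).str.strip()
    if meta["sample_id"].duplicated().any():
        raise InputError(f"{path}: duplicate sample_id in metadata")
    if meta["tissue_class"].isna().any():
        raise InputError(f"{path}: tissue_class missing for some samples")
    bad = set(meta["tissue_class"]) - {"tumor", "non_tumor"}
    if bad:
        raise InputError(f"{path}: unknown tissue_class value(s) {sorted(bad)}")
    for col in ("time_months", "event", "age_years", "stage"):
        if col in meta.columns:
            meta[col] = pd.to_numeric(meta[col], errors="coerce")
    meta = meta.set_index("sample_id", drop=False)
    if expression_samples is not None:
        missing = [s for s in expression_samples if s not in meta.index]
        if missing:
            logger.warning(
                "%d expression sample(s) have no metadata: %s",
                len(missing), missing[:10],
            )
        meta = meta.reindex([s for s in expression_samples if s in meta.index])
    return meta


def read_matrisome_annotation(path) -> pd.DataFrame:
    """Read the matrisome annotation (gene, division, category).

    Categories must be consistent with the division: collagens, proteoglycans
    and ECM glycoproteins are core matrisome; the rest matrisome-associated.
    """
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "division", "category"}
    if not required.issubset(ann.columns):
        raise InputError(f"{path}: annotation requires columns {sorted(required)}")
    ann["gene"] = _normalize_symbols(ann["gene"])
    if ann["gene"].duplicated().any():
        raise InputError(f"{path}: duplicate gene in matrisome annotation")
    bad_div = set(ann["division"]) - {"core_matrisome", "matrisome_associated"}
    if bad_div:
        raise InputError(f"{path}: unknown division value(s) {sorted(bad_div)}")
    bad_cat = set(ann["category"]) - CORE_CATEGORIES - ASSOCIATED_CATEGORIES
    if bad_cat:
        raise InputError(f"{path}: unknown category value(s) {sorted(bad_cat)}")
    is_core_cat = ann["category"].isin(CORE_CATEGORIES)
    is_core_div = ann["division"] == "core_matrisome"
    if (is_core_cat != is_core_div).any():
        off = ann.loc[is_core_cat != is_core_div, "gene"].tolist()
        raise InputError(f"{path}: category inconsistent with division for {off[:10]}")
    return ann.set_index("gene", drop=False)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *genes = fields
            if name in sets:
                raise InputError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes = [g.strip().upper() for g in genes if g.strip()]
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def read_ligand_receptor_table(path, matrisome: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read ligand-receptor pairs (ligand, receptor, receptor_class, pathways).

    ``pathways`` is semicolon-delimited. When a matrisome annotation is given,
    ligands are restricted to the core-matrisome division (pairs with other
    ligands are dropped and reported).
    """
    pairs = pd.read_csv(path, sep="\t", dtype=str, na_values=list(NA_STRINGS),
                        keep_default_na=False)
    required = {"ligand", "receptor", "receptor_class"}
    if not required.issubset(pairs.columns):
        raise InputError(f"{path}: pair table requires columns {sorted(required)}")
    pairs["ligand"] = _normalize_symbols(pairs["ligand"])
    pairs["receptor"] = _normalize_symbols(pairs["receptor"])
    if "pathways" not in pairs.columns:
        pairs["pathways"] = ""
    pairs["pathways"] = pairs["pathways"].fillna("")
    if pairs.duplicated(subset=["ligand", "receptor"]).any():
        raise InputError(f"{path}: duplicate (ligand, receptor) pair")
    if matrisome is not None:
        core = set(matrisome.loc[matrisome["division"] == "core_matrisome", "gene"])
        keep = pairs["ligand"].isin(core)
        if (~keep).any():
            logger.info(
                "dropped %d pair(s) whose ligand is not core matrisome",
                int((~keep).sum()),
            )
        pairs = pairs.loc[keep].reset_index(drop=True)
    return pairs


def read_fibrosis_signature(path) -> pd.DataFrame:
    """Read a +/-1-weighted gene signature (columns: gene, weight)."""
    sig = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if not {"gene", "weight"}.issubset(sig.columns):
        raise InputError(f"{path}: fibrosis signature requires gene and weight columns")
    sig["gene"] = _normalize_symbols(sig["gene"])
    sig["weight"] = pd.to_numeric(sig["weight"], errors="coerce")
    if sig["gene"].duplicated().any():
        raise InputError(f"{path}: duplicate gene in fibrosis signature")
    if not sig["weight"].isin([1, -1]).all():
        raise InputError(f"{path}: fibrosis weights must be +1 or -1")
    return sig.set_index("gene", drop=False)
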