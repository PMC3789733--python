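"""Readers, writers and alignment for expression matrices and sample metadata.

The expression format is a plain tab-delimited matrix with probesets/genes in
rows and samples in columns (log2 scale, e.g. GCRMA output). Metadata is a
tab-delimited table with columns ``sample_id``, ``age`` and optionally ``sex``.
All readers transparently accept gzip-compressed files.

Missing expression values are a hard error: every downstream contingency
count assumes a complete matrix, and silent imputation would change those
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SEX_LABELS = ("F", "M", "unknown")


@dataclass
class ExpressionDataset:
    """A log2 expression matrix (genes x samples) with optional per-sample
    age (years) and sex annotations."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    ages: np.ndarray | None = None
    sex: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if self.ages is not None:
            self.ages = np.asarray(self.ages, dtype=float)
            if self.ages.shape != (len(self.sample_ids),):
                raise ValueError("ages length does not match sample count")
            if not np.all(np.isfinite(self.ages)) or np.any(self.ages <= 0):
                raise ValueError("ages must be finite and > 0")
        if self.sex is not None:
            self.sex = np.asarray(self.sex, dtype=object)
            if self.sex.shape != (len(self.sample_ids),):
                raise ValueError("sex length does not match sample count")
            bad = set(self.sex) - set(_SEX_LABELS)
            if bad:
                raise ValueError(f"unrecognized sex labels: {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, index: np.ndarray) -> "ExpressionDataset":
        """Column subset/reorder by integer positions."""
        index = np.asarray(index, dtype=int)
        return ExpressionDataset(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in index],
            values=self.values[:, index],
            ages=None if self.ages is None else self.ages[index],
            sex=None if self.sex is None else self.sex[index],
        )

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionDataset":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:5]}")
        idx = [pos[g] for g in gene_ids]
        return replace(
            self, gene_ids=list(gene_ids), values=self.values[idx, :]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


def read_expression(path) -> ExpressionDataset:
    """Read a genes-x-samples TSV matrix (first row sample ids, first column
    gene ids). Ages/sex are left unset; use :func:`read_metadata` +
    :func:`align`."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in raw.index]
    sample_ids = [str(s) for s in raw.columns]
    _check_unique(gene_ids, "gene id")
    _check_unique(sample_ids, "sample id")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if raw[col].isna().any():
            i = int(np.argmax(raw[col].isna().to_numpy()))
            raise ValueError(
                f"missing expression value at row {gene_ids[i]!r}, "
                f"column {col!r}"
            )
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"non-numeric cell {raw[col].iloc[i]!r} at row "
                f"{gene_ids[i]!r}, column {col!r}"
            )
        values[:, j] = converted.to_numpy()
    return ExpressionDataset(gene_ids, sample_ids, values)


def write_expression(dataset: ExpressionDataset, path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata: columns sample_id, age (years), sex
    (F/M, optional; defaults to 'unknown')."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "age" not in cols:
        raise ValueError("metadata must contain sample_id and age columns")
    out = pd.DataFrame(
        {
            "sample_id": df[cols["sample_id"]].astype(str),
            "age": pd.to_numeric(df[cols["age"]], errors="coerce"),
        }
    )
    if out["age"].isna().any():
        sid = out.loc[out["age"].isna(), "sample_id"].iloc[0]
        raise ValueError(f"missing or non-numeric age for sample {sid!r}")
    if (out["age"] <= 0).any():
        sid = out.loc[out["age"] <= 0, "sample_id"].iloc[0]
        raise ValueError(f"non-positive age for sample {sid!r}")
    if "sex" in cols:
        sex = df[cols["sex"]].astype(str).str.strip().str.upper()
        sex = sex.where(sex.isin(["F", "M"]), "unknown")
        sex = sex.replace({"F": "F", "M": "M"})
        out["sex"] = sex.to_numpy()
    else:
        out["sex"] = "unknown"
    _check_unique(list(out["sample_id"]), "sample id")
    return out


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def align(dataset: ExpressionDataset, metadata: pd.DataFrame) -> ExpressionDataset:
    """Attach ages/sex to the expression matrix, reordering columns to the
    metadata row order. Samples absent from either side are dropped (the
    count is logged); an empty intersection is an error."""
    expr_pos = {s: i for i, s in enumerate(dataset.sample_ids)}
    keep = metadata[metadata["sample_id"].isin(expr_pos)].reset_index(drop=True)
    if keep.empty:
        raise ValueError("no samples shared between expression and metadata")
    dropped_meta = len(metadata) - len(keep)
    dropped_expr = dataset.n_samples - len(keep)
    if dropped_meta or dropped_expr:
        logger.info(
            "align: dropped %d metadata-only and %d expression-only samples",
            dropped_meta,
            dropped_expr,
        )
    idx = np.array([expr_pos[s] for s in keep["sample_id"]], dtype=int)
    aligned = dataset.subset_samples(idx)
    aligned.ages = keep["age"].to_numpy(dtype=float)
    aligned.sex = keep["sex"].to_numpy(dtype=object)
    return ExpressionDataset(
        aligned.gene_ids, aligned.sample_ids, aligned.values,
        ages=keep["age"].to_numpy(dtype=float),
        sex=keep["sex"].to_numpy(dtype=object),
    )


def read_gene_map(path) -> dict[str, str]:
    """Optional two-column probeset -> gene-symbol map (TSV, no header
    required if exactly two columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if df.shape[1] < 2:
        raise ValueError("gene map must have two tab-separated columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
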