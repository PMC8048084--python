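"""Expression-matrix and drug-response containers and the integration transforms.

The pipeline standardizes expression data so that cell-line and tissue
transcriptomes are comparable: duplicate gene symbols are collapsed by
averaging on the raw scale, values are log2(x+1)-transformed, and every
sample (column) is Z-scored across genes so that each sample has mean 0
and standard deviation 1.  Drug response is carried as per-(drug, cell
line) ln(IC50) observations tagged with their screen release; when the
same pair is assayed in both releases, the newer (GDSC2-style) record
supersedes the older one.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DrugResponseTable",
    "DrugDataset",
    "ExpressionParseError",
    "IntegrationError",
    "load_expression",
    "write_expression",
    "collapse_duplicate_symbols",
    "log2p1_transform",
    "zscore_per_sample",
    "load_drug_responses",
    "merge_drug_releases",
    "build_drug_dataset",
    "attach_external",
    "load_sample_metadata",
    "write_provenance",
]

TRANSFORM_STATES = ("raw", "log2p1", "zscore")


class ExpressionParseError(ValueError):
    """Malformed expression input (bad header, non-numeric cell, empty matrix)."""


class IntegrationError(ValueError):
    """Invalid combination of inputs (no overlap, wrong transform state, ...)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with per-sample metadata.

    ``values`` is a pandas DataFrame indexed by gene symbol with sample
    identifiers as columns.  ``transform_state`` records where the matrix
    sits in the raw -> log2p1 -> zscore chain.  ``meta``, when present, is
    indexed by sample id and carries ``source_class`` (cell_line / tumor /
    normal), ``tissue_type`` and an optional ``subtype`` column.
    """

    values: pd.DataFrame
    transform_state: str = "raw"
    meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.transform_state not in TRANSFORM_STATES:
            raise ValueError(f"unknown transform_state {self.transform_state!r}")
        if not self.values.columns.is_unique:
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ExpressionParseError(f"duplicate sample ids: {dups[:5]}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ExpressionParseError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_state(self, state: str, op: str) -> None:
        if self.transform_state != state:
            raise IntegrationError(
                f"{op} requires transform_state={state!r}, got {self.transform_state!r}"
            )


@dataclass
class DrugResponseTable:
    """Per-(drug, cell line) ln(IC50) observations with a release tag."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("drug_id", "cell_line_id", "ln_ic50", "release") if c not in self.records.columns]
        if missing:
            raise IntegrationError(f"drug-response table missing columns {missing}")
        if not np.isfinite(self.records["ln_ic50"].to_numpy(dtype=float)).all():
            raise IntegrationError("non-finite ln_ic50 value in drug-response table")

    def for_drug(self, drug_id) -> pd.DataFrame:
        return self.records[self.records["drug_id"].astype(str) == str(drug_id)]

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.records["drug_id"].astype(str).unique())


@dataclass
class DrugDataset:
    """Aligned per-drug dataset: z-scored cell-line expression and ln(IC50).

    ``X`` holds the cell lines that have a response for this drug, columns
    sorted lexicographically by cell-line id; ``y`` is index-aligned to the
    columns of ``X``.  ``external`` optionally carries tumor/normal samples
    z-scored through the identical transform chain and restricted to the
    common gene universe.
    """

    drug_id: str
    X: ExpressionMatrix
    y: pd.Series
    external: Optional[ExpressionMatrix] = None

    def __post_init__(self) -> None:
        if list(self.y.index) != self.X.sample_ids:
            raise IntegrationError("y is not aligned with the columns of X")
        if self.external is not None and self.external.gene_ids != self.X.gene_ids:
            raise IntegrationError("external gene universe differs from cell-line matrix")

    @property
    def n_cell_lines(self) -> int:
        return self.X.n_samples


# ---------------------------------------------------------------------------
# readers / writers


def _finalize_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ExpressionParseError(f"{path}: empty expression matrix")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ExpressionParseError(
                f"{path}: non-numeric value {df.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
            )
        df[col] = coerced.astype(float)
    return df


def load_expression(path, dialect: str = "tsv_matrix", meta: Optional[pd.DataFrame] = None) -> ExpressionMatrix:
    """Read a genes-x-samples matrix from plain TSV or GCT 1.2 text.

    TSV: first column gene symbols, header row of sample ids.  GCT: a
    ``#1.2`` line, a dimensions line, then Name/Description columns ahead
    of the samples.  Duplicate symbols are preserved (collapse them with
    :func:`collapse_duplicate_symbols` before merging).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv_matrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        df.index = df.index.astype(str)
    elif dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise ExpressionParseError(f"{path}: expected '#1.2' GCT version line, got {version!r}")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise ExpressionParseError(f"{path}: malformed GCT dimensions line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", dtype=str)
        if df.shape[1] < 2 + n_samples:
            raise ExpressionParseError(f"{path}: GCT header declares {n_samples} samples, fewer columns found")
        df = df.set_index(df.columns[0]).drop(columns=[df.columns[1]])
        df.index = df.index.astype(str)
        if df.shape != (n_genes, n_samples):
            raise ExpressionParseError(
                f"{path}: GCT dimensions line says {n_genes}x{n_samples}, body is {df.shape[0]}x{df.shape[1]}"
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _finalize_frame(df, path)
    df.index.name = None
    df.columns.name = None
    # duplicate genes allowed at this stage; duplicate samples are never valid
    return ExpressionMatrix(values=df, transform_state="raw", meta=meta)


def write_expression(m: ExpressionMatrix, path, dialect: str = "tsv_matrix") -> None:
    """Write the matrix as decimal text (round-trips through load_expression)."""
    path = Path(path)
    if dialect == "tsv_matrix":
        out = m.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.17g")
    elif dialect == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{m.n_genes}\t{m.n_samples}\n")
            body = m.values.copy()
            body.insert(0, "Description", "na")
            body.index.name = "Name"
            body.to_csv(fh, sep="\t", float_format="%.17g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def load_drug_responses(path, release: Optional[str] = None) -> DrugResponseTable:
    """Read a drug-response TSV (drug_id, drug_name, putative_target, cell_line_id, ln_ic50, release)."""
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "cell_line_id": str})
    if release is not None:
        df = df[df["release"] == release].copy()
    return DrugResponseTable(records=df.reset_index(drop=True))


def load_sample_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata TSV (sample_id, source_class, tissue_type[, subtype])."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    if "subtype" not in df.columns:
        df["subtype"] = pd.NA
    return df


# ---------------------------------------------------------------------------
# transforms


def collapse_duplicate_symbols(m: ExpressionMatrix) -> ExpressionMatrix:
    """Average the rows of a repeated gene symbol; keep first-occurrence order."""
    m.require_state("raw", "collapse_duplicate_symbols")
    if m.values.index.is_unique:
        return m
    order = m.values.index.drop_duplicates()
    collapsed = m.values.groupby(level=0, sort=False).mean().loc[order]
    return ExpressionMatrix(values=collapsed, transform_state="raw", meta=m.meta)


def log2p1_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every value v by log2(v + 1).  Requires nonnegative raw values."""
    m.require_state("raw", "log2p1_transform")
    vals = m.values.to_numpy()
    if (vals < 0).any():
        gi, si = np.argwhere(vals < 0)[0]
        raise IntegrationError(
            f"negative expression value at gene {m.gene_ids[gi]!r}, sample {m.sample_ids[si]!r}"
        )
    out = pd.DataFrame(np.log2(vals + 1.0), index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=out, transform_state="log2p1", meta=m.meta)


def zscore_per_sample(m: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Standardize each sample column across genes: z = (x - mean) / sd.

    Every sample ends with mean 0 and standard deviation 1 across its genes,
    making cell-line and tissue profiles comparable.  ``ddof=1`` (sample
    standard deviation) is the default; set ``ddof=0`` for the population
    convention.
    """
    m.require_state("log2p1", "zscore_per_sample")
    if m.n_genes < 2:
        raise IntegrationError("z-scoring needs at least 2 genes per sample")
    vals = m.values.to_numpy()
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=ddof)
    degenerate = sd == 0
    if degenerate.any():
        bad = [m.sample_ids[i] for i in np.flatnonzero(degenerate)[:5]]
        raise IntegrationError(f"constant expression column(s), cannot z-score: {bad}")
    out = pd.DataFrame((vals - mean) / sd, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=out, transform_state="zscore", meta=m.meta)


def standardize(m: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Full chain: collapse duplicates -> log2(x+1) -> per-sample z-score."""
    return zscore_per_sample(log2p1_transform(collapse_duplicate_symbols(m)), ddof=ddof)


# ---------------------------------------------------------------------------
# merging


def merge_drug_releases(t1: DrugResponseTable, t2: DrugResponseTable) -> DrugResponseTable:
    """Union of two screen releases; the second release wins on shared pairs.

    ``t1`` must be tagged GDSC1 and ``t2`` GDSC2.  Drugs sharing a name but
    carrying distinct drug ids remain distinct drugs.
    """
    for tbl, tag in ((t1, "GDSC1"), (t2, "GDSC2")):
        rel = tbl.records["release"].unique().tolist()
        if rel and rel != [tag]:
            raise IntegrationError(f"expected a pure {tag} table, found releases {rel}")
        dup = tbl.records.duplicated(subset=["drug_id", "cell_line_id"])
        if dup.any():
            pair = tbl.records.loc[dup.idxmax(), ["drug_id", "cell_line_id"]].tolist()
            raise IntegrationError(f"duplicate (drug, cell line) pair within {tag}: {pair}")
    keys2 = set(map(tuple, t2.records[["drug_id", "cell_line_id"]].astype(str).to_numpy()))
    keep1 = ~t1.records[["drug_id", "cell_line_id"]].astype(str).apply(tuple, axis=1).isin(keys2)
    merged = pd.concat([t1.records[keep1], t2.records], ignore_index=True)
    return DrugResponseTable(records=merged)


def build_drug_dataset(expr: ExpressionMatrix, responses: DrugResponseTable, drug_id) -> DrugDataset:
    """Restrict expression to the cell lines assayed for one drug, align ln(IC50).

    Sample order is deterministic (lexicographic by cell-line id) so that
    all downstream randomness depends only on seeds.
    """
    expr.require_state("zscore", "build_drug_dataset")
    rec = responses.for_drug(drug_id)
    shared = sorted(set(expr.sample_ids) & set(rec["cell_line_id"].astype(str)))
    if not shared:
        raise IntegrationError(f"no cell line overlap between expression and responses for drug {drug_id!r}")
    X = ExpressionMatrix(values=expr.values[shared], transform_state="zscore", meta=expr.meta)
    y = rec.set_index(rec["cell_line_id"].astype(str))["ln_ic50"].astype(float).loc[shared]
    y.name = "ln_ic50"
    return DrugDataset(drug_id=str(drug_id), X=X, y=y)


def attach_external(ds: DrugDataset, ext: ExpressionMatrix) -> DrugDataset:
    """Attach tumor/normal samples, reducing both matrices to the common genes.

    Z-scores are NOT recomputed after the gene intersection: each sample was
    standardized over its full transcriptome upstream and keeps those values.
    """
    ext.require_state("zscore", "attach_external")
    common = [g for g in ds.X.gene_ids if g in set(ext.gene_ids)]
    if not common:
        raise IntegrationError("no common genes between cell-line matrix and external samples")
    X = ExpressionMatrix(values=ds.X.values.loc[common], transform_state="zscore", meta=ds.X.meta)
    external = ExpressionMatrix(values=ext.values.loc[common], transform_state="zscore", meta=ext.meta)
    return DrugDataset(drug_id=ds.drug_id, X=X, y=ds.y, external=external)


# ---------------------------------------------------------------------------
# provenance


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(path, *, inputs: Iterable = (), params: Optional[dict] = None, seed: Optional[int] = None) -> None:
    """Write a sidecar JSON recording input hashes, parameters and seeds."""
    record = {
        "inputs": {str(p): file_sha256(p) for p in inputs},
        "params": params or {},
        "seed": seed,
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
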