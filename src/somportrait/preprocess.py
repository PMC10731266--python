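"""Expression-table loading, gene-ID conversion and SOM input normalization.

The training input expected by the SOM is a genes × samples matrix taken
through a fixed sequence of transforms: CPM values are log10-transformed
(with a pseudocount so zeros survive), quantile-normalized so every sample
shares one value distribution, and centralized so each gene profile expresses
deviation from its own mean. The sequence is enforced through a ``scale``
tag carried by :class:`ExpressionMatrix`; calling a transform out of order
raises :class:`PipelineOrderError`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "SCALES",
    "ExpressionMatrix",
    "GeneIDMap",
    "ConversionReport",
    "LoadError",
    "PipelineOrderError",
    "load_expression",
    "load_id_map_from_gff3",
    "load_id_map_from_tsv",
    "convert_and_filter",
    "log10_transform",
    "quantile_normalize",
    "centralize",
    "normalize_for_som",
    "read_sample_sheet",
]

#: Allowed scale tags, in pipeline order.
SCALES = ("cpm", "log10", "log10-qnorm", "log10-qnorm-centered")


class LoadError(ValueError):
    """Raised when an input file cannot be turned into a valid object."""


class PipelineOrderError(ValueError):
    """Raised when a transform is applied to a matrix on the wrong scale."""


def _require_scale(matrix: "ExpressionMatrix", expected: str, op: str) -> None:
    if matrix.scale != expected:
        raise PipelineOrderError(
            f"{op} expects a matrix on scale '{expected}', got '{matrix.scale}'"
        )


@dataclass
class ExpressionMatrix:
    """Genes × samples abundance table with a scale tag.

    Parameters
    ----------
    df :
        DataFrame indexed by unique gene IDs with unique sample-ID columns.
        Values must be numeric and free of missing entries.
    scale :
        One of :data:`SCALES`; updated by every transform.
    """

    df: pd.DataFrame
    scale: str = "cpm"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale tag '{self.scale}'")
        if self.df.shape[0] == 0 or self.df.shape[1] == 0:
            raise ValueError("expression matrix must have at least one gene and one sample")
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise LoadError(f"duplicate gene ID '{dup}'")
        if self.df.columns.has_duplicates:
            dup = self.df.columns[self.df.columns.duplicated()][0]
            raise LoadError(f"duplicate sample ID '{dup}'")
        values = self.df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise LoadError("expression matrix contains non-numeric values")
        if np.isnan(values).any():
            g, s = np.argwhere(np.isnan(values))[0]
            raise LoadError(
                f"missing value at gene '{self.df.index[g]}', sample '{self.df.columns[s]}'"
            )
        if self.scale == "cpm" and (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise LoadError(
                f"negative CPM at gene '{self.df.index[g]}', sample '{self.df.columns[s]}'"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.df.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.columns

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.df.shape[0]

    @property
    def n_samples(self) -> int:
        return self.df.shape[1]

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")
        return path


@dataclass(frozen=True)
class GeneIDMap:
    """Partial old-ID → new-ID mapping with provenance.

    New IDs must be unique among mapped entries; a collision means two source
    genes would silently merge, so it is surfaced as :class:`LoadError`.
    """

    entries: Mapping[str, str]
    source: str = ""
    n_skipped: int = 0

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for old, new in self.entries.items():
            if new in seen:
                raise LoadError(
                    f"gene-ID map collision: '{seen[new]}' and '{old}' both map to '{new}'"
                )
            seen[new] = old
        object.__setattr__(self, "entries", dict(self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, old_id: str) -> bool:
        return old_id in self.entries

    def __getitem__(self, old_id: str) -> str:
        return self.entries[old_id]


@dataclass(frozen=True)
class ConversionReport:
    """Audit trail of :func:`convert_and_filter`."""

    n_input: int
    n_kept: int
    n_dropped: int
    dropped_ids: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dropped_gene_id": list(self.dropped_ids)})


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

def load_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read a CPM expression table (genes as rows, samples as header).

    ``format`` is one of ``tsv``, ``csv``, ``xlsx``; inferred from the file
    suffix when omitted. Duplicate gene rows and non-numeric cells are
    rejected with errors naming the offending gene/cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".xlsx": "xlsx"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise LoadError(f"cannot infer format from suffix '{path.suffix}'")
    if format == "tsv":
        raw = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "csv":
        raw = pd.read_csv(path, index_col=0)
    elif format == "xlsx":
        raw = pd.read_excel(path, index_col=0)
    else:
        raise LoadError(f"unsupported format '{format}'")

    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise LoadError(f"duplicate gene ID '{dup}' in {path.name}")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise LoadError(
            f"non-numeric value {raw.iat[g, s]!r} at gene '{raw.index[g]}', "
            f"sample '{raw.columns[s]}' in {path.name}"
        )
    return ExpressionMatrix(numeric, scale="cpm")


def load_id_map_from_gff3(
    path: str | Path, old_attr_key: str, new_attr_key: str, feature_type: str = "gene"
) -> GeneIDMap:
    """Build a gene-ID map from attributes of ``gene`` features in a GFF3 file.

    One entry is produced per feature carrying both attribute keys; features
    missing either key are skipped and counted in ``n_skipped``. Malformed
    feature lines raise :class:`LoadError` with the line number.
    """
    path = Path(path)
    entries: dict[str, str] = {}
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise LoadError(
                    f"malformed GFF3 line {lineno} in {path.name}: expected 9 fields"
                )
            try:
                feature = gffutils.feature.feature_from_line(line)
            except Exception as exc:
                raise LoadError(f"malformed GFF3 line {lineno} in {path.name}: {exc}") from exc
            if feature.featuretype != feature_type:
                continue
            old = feature.attributes.get(old_attr_key)
            new = feature.attributes.get(new_attr_key)
            if not old or not new:
                n_skipped += 1
                continue
            entries[old[0]] = new[0]
    return GeneIDMap(entries, source=str(path), n_skipped=n_skipped)


def load_id_map_from_tsv(path: str | Path) -> GeneIDMap:
    """Read a two-column (old_id, new_id) TSV without header."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if frame.shape[1] < 2:
        raise LoadError(f"{path.name}: expected two tab-separated columns")
    entries = dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))
    return GeneIDMap(entries, source=str(path))


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV with columns sample_id, cultivar, condition, replicate."""
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "cultivar", "condition", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise LoadError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise LoadError("duplicate sample_id in sample sheet")
    return sheet


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def convert_and_filter(
    matrix: ExpressionMatrix, idmap: GeneIDMap
) -> tuple[ExpressionMatrix, ConversionReport]:
    """Re-key the matrix to new gene IDs, dropping genes absent from the map.

    Conservation holds by construction: kept + dropped = input genes. An empty
    result (no gene mapped) is an error rather than an empty matrix.
    """
    _require_scale(matrix, "cpm", "convert_and_filter")
    mapped_mask = matrix.gene_ids.isin(idmap.entries)
    dropped = tuple(matrix.gene_ids[~mapped_mask])
    kept = matrix.df.loc[mapped_mask].copy()
    if kept.shape[0] == 0:
        raise LoadError("no gene of the matrix is covered by the ID map")
    kept.index = pd.Index([idmap[g] for g in kept.index], name=kept.index.name)
    out = ExpressionMatrix(kept, scale="cpm")
    report = ConversionReport(
        n_input=matrix.n_genes, n_kept=out.n_genes, n_dropped=len(dropped), dropped_ids=dropped
    )
    return out, report


def log10_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log10(x + pseudocount); with the default pseudocount zero maps to zero."""
    _require_scale(matrix, "cpm", "log10_transform")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    out = pd.DataFrame(
        np.log10(matrix.values + pseudocount), index=matrix.gene_ids, columns=matrix.sample_ids
    )
    return ExpressionMatrix(out, scale="log10")


def _quantile_normalize_values(values: np.ndarray) -> np.ndarray:
    """Sorted-mean quantile normalization with tie-blocks averaged per column."""
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        target = reference.copy()
        sorted_col = col[order]
        # average the reference over runs of tied input values
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        for start, stop in zip(np.r_[0, boundaries], np.r_[boundaries, len(col)]):
            if stop - start > 1:
                target[start:stop] = target[start:stop].mean()
        out[order, j] = target
    return out


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common sorted-mean distribution.

    Ties within a column receive the average of their target quantile values.
    A single-sample matrix is returned unchanged with a warning (there is
    nothing to normalize against).
    """
    _require_scale(matrix, "log10", "quantile_normalize")
    if matrix.n_samples == 1:
        warnings.warn("quantile normalization of a single-sample matrix is a no-op")
        return ExpressionMatrix(matrix.df.copy(), scale="log10-qnorm")
    out = pd.DataFrame(
        _quantile_normalize_values(matrix.values),
        index=matrix.gene_ids,
        columns=matrix.sample_ids,
    )
    return ExpressionMatrix(out, scale="log10-qnorm")


def centralize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean across samples (rows become zero-mean)."""
    _require_scale(matrix, "log10-qnorm", "centralize")
    values = matrix.values
    out = pd.DataFrame(
        values - values.mean(axis=1, keepdims=True),
        index=matrix.gene_ids,
        columns=matrix.sample_ids,
    )
    return ExpressionMatrix(out, scale="log10-qnorm-centered")


def normalize_for_som(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Full CPM → centered pipeline: log10, quantile normalize, centralize."""
    return centralize(quantile_normalize(log10_transform(matrix, pseudocount)))
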