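"""Gene-set statistics for spot modules and samples.

Overrepresentation of a gene set inside a spot's gene list is tested with the
exact hypergeometric upper tail against the analysis universe (by default all
genes that entered SOM training), with Benjamini–Hochberg adjustment across
the full spot × set table. Per-sample set activity is summarized by a
one-sample location Z-score of the set genes against the sample-wide
expression distribution. Gene sets are exchanged in GMT format.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .portraits import SpotModule
from .preprocess import ExpressionMatrix

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt_sets",
    "overrepresentation",
    "enrich_all",
    "top_sets_per_spot",
    "gene_set_zscore",
    "zscore_table",
    "top_genes",
    "setcount_per_spot",
]


@dataclass(frozen=True)
class GeneSet:
    """Named collection of unique gene IDs."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set '{self.name}' is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric overrepresentation of one set in one spot."""

    spot_label: str
    set_name: str
    k: int  # overlap
    n: int  # spot size (within universe)
    K: int  # set size within universe
    N: int  # universe size
    p_value: float
    adj_p: float | None = None


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members per line)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{Path(path).name}:{lineno}: GMT line needs >= 3 fields")
            sets.append(GeneSet(fields[0], frozenset(fields[2:]), description=fields[1]))
    return sets


def write_gmt_sets(sets: Sequence[GeneSet], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or s.name, *sorted(s.members)]) + "\n")
    return path


def overrepresentation(
    spot_genes: Iterable[str], gene_set: GeneSet, universe: Iterable[str]
) -> EnrichmentResult:
    """Exact hypergeometric upper-tail test P[X ≥ k] of one set in one spot.

    The set is intersected with the universe before testing; the spot's genes
    must be a subset of the universe.
    """
    universe = set(universe)
    spot = set(spot_genes)
    if not universe:
        raise ValueError("enrichment universe is empty")
    if not spot:
        raise ValueError("spot gene list is empty")
    stray = spot - universe
    if stray:
        raise ValueError(f"spot genes outside the universe: {sorted(stray)[:5]}")
    members = gene_set.members & universe
    k = len(spot & members)
    N, K, n = len(universe), len(members), len(spot)
    # upper tail P[X >= k]; sf(k-1) is exact, no normal approximation
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return EnrichmentResult("", gene_set.name, k, n, K, N, p)


def enrich_all(
    spot_catalog: Sequence[SpotModule],
    gene_sets: Sequence[GeneSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Test every (spot, set) pair; BH-adjust across the whole table.

    Returns a tidy frame sorted by spot then raw p, with columns
    spot, set, k, n, K, N, p_value, adj_p.
    """
    if not gene_sets:
        raise ValueError("gene set collection is empty")
    universe = set(universe)
    rows = []
    for spot in spot_catalog:
        for gs in gene_sets:
            res = overrepresentation(spot.member_genes, gs, universe)
            rows.append((spot.label, gs.name, res.k, res.n, res.K, res.N, res.p_value))
    table = pd.DataFrame(rows, columns=["spot", "set", "k", "n", "K", "N", "p_value"])
    table["adj_p"] = stats.false_discovery_control(table["p_value"].to_numpy(), method="bh")
    table["adj_p"] = np.minimum(1.0, np.maximum(table["adj_p"], table["p_value"]))
    return table.sort_values(["spot", "p_value", "set"], kind="stable").reset_index(drop=True)


def top_sets_per_spot(table: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Top-k gene sets per spot by raw p-value (ranking view of enrich_all)."""
    if k <= 0:
        raise ValueError("k must be positive")
    return (
        table.sort_values(["spot", "p_value", "set"], kind="stable")
        .groupby("spot", sort=False)
        .head(k)
        .reset_index(drop=True)
    )


def gene_set_zscore(matrix: ExpressionMatrix, gene_set: GeneSet) -> pd.Series:
    """Per-sample location Z-score of the set genes vs. the whole sample.

    z_s = (mean of set genes in sample s − mean of all genes in s)
          / (sd of all genes in s / sqrt(m)),  m = |set ∩ matrix genes|.

    Requires the centered log-scale matrix so that z expresses set-specific
    deviation rather than library depth.
    """
    if matrix.scale != "log10-qnorm-centered":
        raise ValueError("gene_set_zscore expects the centered matrix "
                         f"(scale 'log10-qnorm-centered', got '{matrix.scale}')")
    members = [g for g in matrix.gene_ids if g in gene_set.members]
    if not members:
        raise ValueError(f"gene set '{gene_set.name}' has no gene in the matrix")
    values = matrix.values
    set_mean = matrix.df.loc[members].mean(axis=0)
    all_mean = values.mean(axis=0)
    all_sd = values.std(axis=0, ddof=1)
    z = (set_mean.to_numpy() - all_mean) / (all_sd / np.sqrt(len(members)))
    return pd.Series(z, index=matrix.sample_ids, name=gene_set.name)


def zscore_table(matrix: ExpressionMatrix, gene_sets: Sequence[GeneSet]) -> pd.DataFrame:
    """Sets × samples Z-score table (sets without matrix genes are skipped)."""
    rows = []
    for gs in gene_sets:
        if not any(g in gs.members for g in matrix.gene_ids):
            continue
        rows.append(gene_set_zscore(matrix, gs))
    return pd.DataFrame(rows)


def top_genes(
    spot: SpotModule,
    matrix: ExpressionMatrix,
    group_samples: Sequence[str],
    k: int = 20,
) -> pd.DataFrame:
    """Spot genes ranked by mean centered expression over a sample group.

    Ties are broken by gene ID so the ranking is stable; k larger than the
    spot returns the full list.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    missing = [g for g in spot.member_genes if g not in matrix.df.index]
    if missing:
        raise KeyError(f"spot genes missing from the matrix: {missing[:5]}")
    scores = matrix.df.loc[list(spot.member_genes), list(group_samples)].mean(axis=1)
    ranked = scores.to_frame("score").rename_axis("gene_id").reset_index()
    ranked = ranked.sort_values(["score", "gene_id"], ascending=[False, True], kind="stable")
    return ranked.head(k).reset_index(drop=True)


def setcount_per_spot(
    spot_catalog: Sequence[SpotModule], gene_set: GeneSet
) -> pd.Series:
    """|spot ∩ set| per catalog spot; zero counts are kept."""
    return pd.Series(
        {s.label: len(set(s.member_genes) & gene_set.members) for s in spot_catalog},
        name=gene_set.name,
        dtype=int,
    )
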