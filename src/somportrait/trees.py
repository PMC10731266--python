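"""Sample similarity in metagene space, neighbor-joining trees, clade reports.

Samples are compared through their metagene profiles (codebook columns), by
default with the correlation distance 1 − Pearson, which matches portrait
similarity semantics; Euclidean distance and gene-space profiles are
available alternatives. The classical neighbor-joining agglomeration builds
an unrooted tree; for clade counting the tree is midpoint-rooted and each
condition's "major clade" is identified, flagging samples that fall outside
it as out-grouped (transition-state candidates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .som import SOMModel

__all__ = [
    "sample_distances",
    "profile_distances",
    "neighbor_joining",
    "CladeReport",
    "condition_clades",
    "assign_conditions_by_profile",
]


def profile_distances(profiles: pd.DataFrame, metric: str = "correlation") -> DistanceMatrix:
    """Pairwise sample distances over the columns of a features × samples table.

    ``correlation`` is 1 − Pearson (range [0, 2]); a zero-variance sample is
    an error because its correlation is undefined. ``euclidean`` is the usual
    L2 distance on the profiles.
    """
    labels = [str(c) for c in profiles.columns]
    values = profiles.to_numpy(dtype=float)
    if metric == "correlation":
        sd = values.std(axis=0)
        dead = np.flatnonzero(sd < 1e-15)
        if dead.size:
            raise ValueError(
                f"zero-variance sample(s) under correlation metric: "
                f"{[labels[i] for i in dead]}"
            )
        d = 1.0 - np.corrcoef(values.T)
    elif metric == "euclidean":
        diff = values.T[:, None, :] - values.T[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
    else:
        raise ValueError(f"unknown metric '{metric}'")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return DistanceMatrix(d, ids=labels)


def sample_distances(model: SOMModel, metric: str = "correlation") -> DistanceMatrix:
    """Distances between samples on their metagene (codebook-column) profiles."""
    profiles = pd.DataFrame(model.codebook, columns=list(model.sample_ids))
    return profile_distances(profiles, metric)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Classical neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q_ij = (n−2)·d_ij − r_i − r_j is joined;
    ties are broken by the lexicographically smallest label pair, where an
    internal node is represented by the smallest leaf label beneath it.
    Branch lengths follow the standard NJ formulas; negative lengths are
    clamped to zero with a warning. The result is an unrooted tree with a
    trifurcating root node.
    """
    ids = list(dist.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")

    d: dict[int, dict[int, float]] = {}
    nodes: dict[int, TreeNode] = {}
    rep: dict[int, str] = {}
    for i, name in enumerate(ids):
        nodes[i] = TreeNode(name=name)
        rep[i] = name
    for i in range(len(ids)):
        d[i] = {j: float(dist[i, j]) for j in range(len(ids)) if j != i}

    clamped = False
    next_id = len(ids)
    while len(nodes) > 3:
        active = sorted(nodes)
        n = len(active)
        r = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (n - 2) * d[i][j] - r[i] - r[j]
                key = (q, tuple(sorted((rep[i], rep[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d[i][j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            clamped = True
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode()
        parent.extend([nodes[i], nodes[j]])
        new_d = {k: (d[i][k] + d[j][k] - dij) / 2.0 for k in active if k not in (i, j)}
        for k in list(d):
            d[k].pop(i, None)
            d[k].pop(j, None)
        del d[i], d[j], nodes[i], nodes[j]
        nodes[next_id] = parent
        rep[next_id] = min(rep.pop(i), rep.pop(j))
        d[next_id] = new_d
        for k, v in new_d.items():
            d[k][next_id] = v
        next_id += 1

    a, b, c = sorted(nodes)
    la = (d[a][b] + d[a][c] - d[b][c]) / 2.0
    lb = (d[a][b] + d[b][c] - d[a][c]) / 2.0
    lc = (d[a][c] + d[b][c] - d[a][b]) / 2.0
    if min(la, lb, lc) < 0:
        clamped = True
    nodes[a].length = max(la, 0.0)
    nodes[b].length = max(lb, 0.0)
    nodes[c].length = max(lc, 0.0)
    if clamped:
        warnings.warn("negative neighbor-joining branch length(s) clamped to 0")
    root = TreeNode()
    root.extend([nodes[a], nodes[b], nodes[c]])
    return root


# ---------------------------------------------------------------------------
# Clade analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CladeReport:
    """Per-condition clade structure of a midpoint-rooted sample tree.

    For each condition the major clade is the clade maximizing the Jaccard
    overlap between its leaves and the condition's samples (ties favor the
    smaller clade). ``n_major_clades`` counts conditions whose major clade
    reaches Jaccard > the threshold (default 0.5, i.e. the clade is mostly
    that condition and holds most of its samples). Out-grouped samples are
    condition members falling outside their condition's major clade.
    """

    per_condition: pd.DataFrame
    outgrouped: tuple[str, ...]
    n_major_clades: int
    jaccard_threshold: float


def condition_clades(
    tree: TreeNode, sample_sheet: pd.DataFrame, jaccard_threshold: float = 0.5
) -> CladeReport:
    """Count condition clades on the midpoint-rooted tree and flag out-grouped samples."""
    condition_of = dict(zip(sample_sheet["sample_id"].astype(str), sample_sheet["condition"]))
    tips = [t.name for t in tree.tips()]
    missing = [t for t in tips if t not in condition_of]
    if missing:
        raise ValueError(f"leaves without condition annotation: {missing}")

    rooted = tree.copy().root_at_midpoint()
    conditions = pd.unique(sample_sheet.loc[sample_sheet["sample_id"].isin(tips), "condition"])

    # tip sets per internal node (plus singleton leaves)
    clades: list[frozenset[str]] = []
    tipsets: dict[int, frozenset[str]] = {}
    for node in rooted.postorder(include_self=True):
        if node.is_tip():
            ts = frozenset([node.name])
        else:
            ts = frozenset().union(*(tipsets[id(ch)] for ch in node.children))
        tipsets[id(node)] = ts
        clades.append(ts)

    rows = []
    outgrouped: list[str] = []
    n_major = 0
    for condition in conditions:
        members = {t for t in tips if condition_of[t] == condition}
        # maximal fully-pure clades
        pure = [c for c in clades if c and all(condition_of[t] == condition for t in c)]
        maximal_pure = [c for c in pure if not any(c < other for other in pure)]
        # major clade: best Jaccard overlap with the condition's sample set
        major = max(
            clades, key=lambda c: (len(c & members) / len(c | members), -len(c))
        )
        jaccard = len(major & members) / len(major | members)
        is_major = jaccard > jaccard_threshold
        if is_major:
            n_major += 1
        out = sorted(members - major) if is_major else sorted(members)
        outgrouped.extend(out)
        rows.append(
            (
                condition,
                len(members),
                len(maximal_pure),
                len(major & members),
                len(major),
                round(jaccard, 4),
                is_major,
                ",".join(out),
            )
        )
    per_condition = pd.DataFrame(
        rows,
        columns=[
            "condition",
            "n_samples",
            "n_pure_clades",
            "major_clade_members",
            "major_clade_size",
            "jaccard",
            "has_major_clade",
            "outgrouped_samples",
        ],
    )
    return CladeReport(
        per_condition=per_condition,
        outgrouped=tuple(outgrouped),
        n_major_clades=n_major,
        jaccard_threshold=jaccard_threshold,
    )


def assign_conditions_by_profile(
    model: SOMModel, sample_sheet: pd.DataFrame
) -> pd.DataFrame:
    """Nearest group-mean metagene profile (Pearson) per sample.

    Returns sample_id, condition (annotated) and predicted_condition; on well
    separated data the two agree for every non-transition sample.
    """
    sheet = sample_sheet.set_index("sample_id")
    profiles = pd.DataFrame(model.codebook, columns=list(model.sample_ids))
    group_means = {
        condition: profiles[list(ids)].mean(axis=1)
        for condition, ids in sheet.groupby("condition").groups.items()
    }
    rows = []
    for sample in profiles.columns:
        best = max(group_means, key=lambda c: np.corrcoef(profiles[sample], group_means[c])[0, 1])
        rows.append((sample, sheet.loc[sample, "condition"], best))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "predicted_condition"])
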