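"""Expression portraits, overexpression spot modules and the spot network.

A portrait is one sample's (or a group mean's) metagene values arranged on
the lattice; it is rendered blue (low) → green (intermediate) → maroon
(high). Spot modules are connected lattice regions above an overexpression
quantile of a portrait; a catalog of spots segmented from several group-mean
portraits is merged into one non-redundant set, and each spot inherits the
genes whose best-matching unit falls inside it. Spot-level expression
profiles feed a weighted-topological-overlap (wTO) network summarizing how
spot activity co-varies across samples.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap
from skimage.measure import label as _cc_label

from .som import SOMModel

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

__all__ = [
    "Portrait",
    "SpotModule",
    "SpotNetwork",
    "PORTRAIT_CMAP",
    "sample_portrait",
    "mean_portrait",
    "condition_portraits",
    "render_portrait",
    "render_portraits",
    "detect_spots",
    "group_spot_summary",
    "spot_expression_profile",
    "spot_profiles",
    "wto_network",
    "spot_catalog_frame",
    "gene_spot_frame",
    "unassigned_genes",
]

#: Low → intermediate → high expression coloring of the portraits.
PORTRAIT_CMAP = LinearSegmentedColormap.from_list(
    "portrait", ["#00008b", "#1e90ff", "#008000", "#d2b42a", "#800000"]
)


@dataclass(frozen=True)
class Portrait:
    """Lattice-shaped metagene values for one sample or sample group."""

    label: str
    values: np.ndarray  # rows × cols

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("portrait values must be a 2-D lattice")
        if not np.isfinite(self.values).all():
            raise ValueError(f"portrait '{self.label}' contains non-finite values")

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SpotModule:
    """Connected overexpressed lattice region with its member genes."""

    label: str
    units: frozenset[tuple[int, int]]
    peak_value: float
    peak_unit: tuple[int, int]
    source_portrait: str
    member_genes: tuple[str, ...] = ()

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_genes(self) -> int:
        return len(self.member_genes)

    def unit_indices(self, cols: int) -> frozenset[int]:
        return frozenset(r * cols + c for r, c in self.units)


@dataclass(frozen=True)
class SpotNetwork:
    """Spot × spot weighted-topological-overlap matrix (plus signed correlations)."""

    labels: tuple[str, ...]
    wto: pd.DataFrame
    correlation: pd.DataFrame

    def __post_init__(self) -> None:
        w = self.wto.to_numpy()
        if not np.allclose(w, w.T):
            raise ValueError("wTO matrix must be symmetric")
        if (w < -1e-9).any() or (w > 1 + 1e-9).any():
            raise ValueError("wTO values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Portraits
# ---------------------------------------------------------------------------

def sample_portrait(model: SOMModel, sample_id: str) -> Portrait:
    """That sample's codebook column reshaped to the lattice (row 0 on top)."""
    try:
        j = model.sample_ids.index(sample_id)
    except ValueError:
        raise KeyError(f"unknown sample '{sample_id}'") from None
    return Portrait(sample_id, model.codebook[:, j].reshape(model.rows, model.cols).copy())


def mean_portrait(portraits: Sequence[Portrait], label: str) -> Portrait:
    """Unit-wise arithmetic mean of portraits sharing one lattice."""
    if len(portraits) == 0:
        raise ValueError("mean_portrait needs at least one portrait")
    shape = portraits[0].values.shape
    if any(p.values.shape != shape for p in portraits):
        raise ValueError("portraits have mismatching lattice dimensions")
    return Portrait(label, np.mean([p.values for p in portraits], axis=0))


def condition_portraits(
    model: SOMModel, sample_groups: Mapping[str, Sequence[str]]
) -> dict[str, Portrait]:
    """Group-mean portrait per group (e.g. per temperature condition)."""
    return {
        group: mean_portrait([sample_portrait(model, s) for s in samples], group)
        for group, samples in sample_groups.items()
    }


def render_portrait(
    portrait: Portrait,
    out_path: str | Path,
    vmin: float | None = None,
    vmax: float | None = None,
    upscale: int = 12,
) -> Path:
    """Write the portrait as a PNG; min → blue, mid → green, max → maroon.

    ``vmin``/``vmax`` pin the color scale (for shared-scale collections);
    ``upscale`` repeats each lattice unit into an upscale × upscale pixel
    block, so pixel dimensions stay proportional to the lattice. The portrait
    itself is never modified.
    """
    out_path = Path(out_path)
    values = portrait.values
    lo = float(values.min()) if vmin is None else float(vmin)
    hi = float(values.max()) if vmax is None else float(vmax)
    if hi - lo < 1e-12:
        hi = lo + 1.0  # constant portrait: single color
    img = np.repeat(np.repeat(values, upscale, axis=0), upscale, axis=1)
    plt.imsave(out_path, img, cmap=PORTRAIT_CMAP, vmin=lo, vmax=hi)
    return out_path


def render_portraits(
    portraits: Sequence[Portrait],
    outdir: str | Path,
    shared_scale: bool = True,
    upscale: int = 12,
) -> dict[str, Path]:
    """Render a collection; with shared_scale one global min/max colors all."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vmin = min(float(p.values.min()) for p in portraits) if shared_scale else None
    vmax = max(float(p.values.max()) for p in portraits) if shared_scale else None
    return {
        p.label: render_portrait(p, outdir / f"portrait_{p.label}.png", vmin, vmax, upscale)
        for p in portraits
    }


# ---------------------------------------------------------------------------
# Spot segmentation
# ---------------------------------------------------------------------------

def detect_spots(
    portrait: Portrait, threshold_quantile: float = 0.98, min_units: int = 4
) -> list[SpotModule]:
    """Segment overexpression spots from one portrait.

    Units at or above the threshold quantile of the portrait's values are
    marked; 8-connected components with at least ``min_units`` units become
    spots, labeled A, B, … in decreasing order of peak value. A constant
    portrait has every unit at the threshold and yields one lattice-spanning
    spot (documented edge case).
    """
    if not 0.0 < threshold_quantile < 1.0:
        raise ValueError("threshold_quantile must be in (0, 1)")
    threshold = np.quantile(portrait.values, threshold_quantile)
    mask = portrait.values >= threshold
    labeled = _cc_label(mask, connectivity=2)
    spots = []
    for cc in range(1, labeled.max() + 1):
        coords = np.argwhere(labeled == cc)
        if len(coords) < min_units:
            continue
        units = frozenset((int(r), int(c)) for r, c in coords)
        peak_unit = min(units, key=lambda rc: (-portrait.values[rc], rc))
        peak = float(portrait.values[peak_unit])
        spots.append(
            SpotModule(
                label="",
                units=units,
                peak_value=peak,
                peak_unit=peak_unit,
                source_portrait=portrait.label,
            )
        )
    spots.sort(key=lambda s: (-s.peak_value, min(s.units)))
    return [replace(s, label=_spot_label(i)) for i, s in enumerate(spots)]


def _spot_label(i: int) -> str:
    letters = string.ascii_uppercase
    if i < len(letters):
        return letters[i]
    return letters[i // len(letters) - 1] + letters[i % len(letters)]


def _genes_in_units(model: SOMModel, units: frozenset[tuple[int, int]]) -> tuple[str, ...]:
    unit_idx = {r * model.cols + c for r, c in units}
    return tuple(g for g, u in zip(model.gene_ids, model.bmu) if int(u) in unit_idx)


def group_spot_summary(
    model: SOMModel,
    sample_groups: Mapping[str, Sequence[str]],
    threshold_quantile: float = 0.98,
    min_units: int = 4,
) -> list[SpotModule]:
    """Non-redundant spot catalog across group-mean portraits.

    Spots are segmented from every group-mean portrait; spots sharing at
    least one lattice unit across groups are merged (union of units). Each
    catalog spot carries the genes whose BMU lies inside it, and spots are
    relabeled A, B, … ordered by first source group, then descending peak.
    """
    seen: dict[str, str] = {}
    for group, samples in sample_groups.items():
        for s in samples:
            if s in seen:
                raise ValueError(f"sample '{s}' appears in groups '{seen[s]}' and '{group}'")
            seen[s] = group

    group_order = {g: i for i, g in enumerate(sample_groups)}
    raw: list[SpotModule] = []
    for group, portrait in condition_portraits(model, sample_groups).items():
        raw.extend(detect_spots(portrait, threshold_quantile, min_units))

    # merge unit-overlapping spots across groups (union–find over spot indices)
    parent = list(range(len(raw)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(raw)):
        for j in range(i + 1, len(raw)):
            if raw[i].units & raw[j].units:
                parent[find(i)] = find(j)

    merged: dict[int, list[SpotModule]] = {}
    for i in range(len(raw)):
        merged.setdefault(find(i), []).append(raw[i])

    catalog = []
    for members in merged.values():
        units = frozenset().union(*(s.units for s in members))
        sources = sorted({s.source_portrait for s in members}, key=group_order.__getitem__)
        top = max(members, key=lambda s: s.peak_value)
        catalog.append(
            SpotModule(
                label="",
                units=units,
                peak_value=top.peak_value,
                peak_unit=top.peak_unit,
                source_portrait="+".join(sources),
                member_genes=_genes_in_units(model, units),
            )
        )
    catalog.sort(
        key=lambda s: (group_order[s.source_portrait.split("+")[0]], -s.peak_value, min(s.units))
    )
    return [replace(s, label=_spot_label(i)) for i, s in enumerate(catalog)]


def unassigned_genes(model: SOMModel, catalog: Sequence[SpotModule]) -> tuple[str, ...]:
    """Genes whose BMU lies outside every catalog spot."""
    assigned = set().union(*(set(s.member_genes) for s in catalog)) if catalog else set()
    return tuple(g for g in model.gene_ids if g not in assigned)


# ---------------------------------------------------------------------------
# Spot profiles and the wTO network
# ---------------------------------------------------------------------------

def spot_expression_profile(model: SOMModel, spot: SpotModule) -> pd.Series:
    """Mean codebook row over the spot's units; one value per sample."""
    idx = sorted(r * model.cols + c for r, c in spot.units)
    return pd.Series(
        model.codebook[idx].mean(axis=0), index=list(model.sample_ids), name=spot.label
    )


def spot_profiles(model: SOMModel, catalog: Sequence[SpotModule]) -> pd.DataFrame:
    """Spots × samples profile table."""
    return pd.DataFrame([spot_expression_profile(model, s) for s in catalog])


def wto_network(profiles: pd.DataFrame) -> SpotNetwork:
    """Weighted topological overlap of spot profiles (rows = spots).

    Adjacency is the absolute Pearson correlation between spot profiles
    (unsigned network; the signed correlations are kept alongside). The
    overlap

        ω_ij = (Σ_u a_iu·a_uj − a_ii·a_ij − a_ij·a_jj + a_ij)
               / (min(k_i, k_j) + 1 − a_ij),  k_i = Σ_{u≠i} a_iu

    rewards spot pairs whose correlation is corroborated by shared neighbors;
    ω is symmetric with values in [0, 1] and a unit diagonal. A constant
    (zero-variance) profile gets zero correlation to everything, with a
    warning.
    """
    if profiles.shape[0] < 2:
        raise ValueError("wto_network needs at least 2 spot profiles")
    values = profiles.to_numpy(dtype=float)
    sd = values.std(axis=1)
    constant = sd < 1e-15
    if constant.any():
        names = [str(profiles.index[i]) for i in np.flatnonzero(constant)]
        warnings.warn(f"constant spot profile(s) {names}: correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)

    a = np.abs(corr)
    k = a.sum(axis=1) - 1.0  # connectivity, self excluded
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = (shared - a) / denom
    omega[~np.isfinite(omega)] = 0.0  # only the diagonal can degenerate (a_ii = 1)
    np.fill_diagonal(omega, 1.0)
    omega = np.clip(omega, 0.0, 1.0)
    omega = (omega + omega.T) / 2.0

    labels = tuple(str(i) for i in profiles.index)
    idx = list(profiles.index)
    return SpotNetwork(
        labels=labels,
        wto=pd.DataFrame(omega, index=idx, columns=idx),
        correlation=pd.DataFrame(corr, index=idx, columns=idx),
    )


# ---------------------------------------------------------------------------
# Tabular exports
# ---------------------------------------------------------------------------

def spot_catalog_frame(catalog: Sequence[SpotModule]) -> pd.DataFrame:
    rows = []
    for s in catalog:
        peak_r, peak_c = s.peak_unit
        rows.append((s.label, s.source_portrait, s.n_units, s.n_genes, s.peak_value,
                     peak_r, peak_c))
    return pd.DataFrame(
        rows,
        columns=["label", "source", "n_units", "n_genes", "peak_value", "peak_row", "peak_col"],
    )


def gene_spot_frame(catalog: Sequence[SpotModule]) -> pd.DataFrame:
    rows = [(g, s.label) for s in catalog for g in s.member_genes]
    return pd.DataFrame(rows, columns=["gene_id", "spot"])
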