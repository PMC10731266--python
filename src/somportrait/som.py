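"""Batch-trained Kohonen map distributing gene expression profiles over a lattice.

Each unit of the quadratic lattice carries a prototype ("metagene") profile
with one value per sample. Training alternates assignment of every gene to its
best-matching unit (BMU, minimal Euclidean distance) with a neighborhood-
weighted recomputation of all prototypes under a Gaussian kernel whose radius
decays exponentially across epochs. Neighboring units end up with correlated
profiles, so co-expressed genes co-localize and appear as smooth structures in
the rendered portraits.

Batch mode with PCA-plane initialization is fully deterministic; an online
(sequential) mode is available for comparison on small inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import cdist

from .preprocess import ExpressionMatrix, PipelineOrderError

__all__ = ["SOMConfig", "SOMModel", "initialize_codebook", "train"]


@dataclass(frozen=True)
class SOMConfig:
    """Lattice geometry and training schedule.

    radius_start defaults to max(rows, cols) / 2 and decays exponentially to
    radius_end over n_epochs; radii are in lattice units.
    """

    rows: int = 40
    cols: int = 40
    n_epochs: int = 50
    radius_start: float | None = None
    radius_end: float = 0.5
    init: str = "pca-linear"
    seed: int = 0
    training_mode: str = "batch"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.radius_end <= 0:
            raise ValueError("radius_end must be > 0")
        if self.radius_start is not None and self.radius_start < self.radius_end:
            raise ValueError("radius_start must be >= radius_end")
        if self.init not in ("pca-linear", "random"):
            raise ValueError(f"unknown init '{self.init}'")
        if self.training_mode not in ("batch", "online"):
            raise ValueError(f"unknown training_mode '{self.training_mode}'")

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    @property
    def radius_start_value(self) -> float:
        if self.radius_start is not None:
            return float(self.radius_start)
        return max(1.0, max(self.rows, self.cols) / 2.0)

    def radius_at(self, epoch: int) -> float:
        """Exponential decay from radius_start to radius_end across epochs."""
        r0, r1 = self.radius_start_value, self.radius_end
        if self.n_epochs == 1:
            return r1
        return r0 * (r1 / r0) ** (epoch / (self.n_epochs - 1))


def _lattice_coords(rows: int, cols: int) -> np.ndarray:
    """Row-major (row, col) coordinates; unit_index = row * cols + col."""
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def _fix_sign(v: np.ndarray) -> np.ndarray:
    # resolve SVD sign ambiguity so pca-linear init is fully deterministic
    return -v if v[np.argmax(np.abs(v))] < 0 else v


def initialize_codebook(matrix: ExpressionMatrix, config: SOMConfig) -> np.ndarray:
    """Initial prototypes, shape (n_units, n_samples).

    ``pca-linear`` lays the prototypes on the plane of the first two principal
    directions of the gene profiles (±2 component standard deviations),
    seed-independent; ``random`` samples gene profiles with the configured
    seed. With fewer than two samples pca-linear falls back to random.
    """
    X = matrix.values
    if config.init == "pca-linear":
        if matrix.n_samples < 2 or matrix.n_genes < 2:
            warnings.warn("pca-linear init needs >= 2 samples and genes; falling back to random")
        else:
            mu = X.mean(axis=0)
            Xc = X - mu
            _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
            v1, v2 = _fix_sign(Vt[0]), _fix_sign(Vt[1])
            s1 = S[0] / np.sqrt(max(matrix.n_genes - 1, 1))
            s2 = S[1] / np.sqrt(max(matrix.n_genes - 1, 1))
            a = np.linspace(-2.0, 2.0, config.rows) if config.rows > 1 else np.zeros(1)
            b = np.linspace(-2.0, 2.0, config.cols) if config.cols > 1 else np.zeros(1)
            codebook = (
                mu[None, None, :]
                + a[:, None, None] * s1 * v1[None, None, :]
                + b[None, :, None] * s2 * v2[None, None, :]
            )
            return codebook.reshape(config.n_units, matrix.n_samples)
    rng = np.random.default_rng(config.seed)
    idx = rng.choice(matrix.n_genes, size=config.n_units, replace=config.n_units > matrix.n_genes)
    return X[idx].copy()


@dataclass
class SOMModel:
    """Trained map: codebook (n_units × n_samples), gene → BMU, and QE history."""

    config: SOMConfig
    codebook: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    bmu: np.ndarray
    quantization_error: float
    qe_history: tuple[float, ...] = ()

    @property
    def rows(self) -> int:
        return self.config.rows

    @property
    def cols(self) -> int:
        return self.config.cols

    @property
    def n_units(self) -> int:
        return self.config.n_units

    def unit_rc(self, unit_index: int) -> tuple[int, int]:
        """Row-major lattice coordinates; row 0 is the top of the portrait."""
        return unit_index // self.cols, unit_index % self.cols

    def map_genes(self, gene_ids: list[str] | None = None) -> pd.DataFrame:
        """Lattice coordinates of each queried gene's BMU."""
        if gene_ids is None:
            gene_ids = list(self.gene_ids)
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"genes not in the trained model: {missing}")
        units = [int(self.bmu[pos[g]]) for g in gene_ids]
        return pd.DataFrame(
            {
                "gene_id": gene_ids,
                "unit_index": units,
                "row": [u // self.cols for u in units],
                "col": [u % self.cols for u in units],
            }
        )

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.codebook, columns=list(self.sample_ids)).to_csv(
            outdir / "codebook.tsv", sep="\t", index_label="unit_index", float_format="%.10g"
        )
        pd.DataFrame({"gene_id": list(self.gene_ids), "unit_index": self.bmu}).to_csv(
            outdir / "bmu.tsv", sep="\t", index=False
        )
        meta = {
            "config": {
                "rows": self.config.rows,
                "cols": self.config.cols,
                "n_epochs": self.config.n_epochs,
                "radius_start": self.config.radius_start,
                "radius_end": self.config.radius_end,
                "init": self.config.init,
                "seed": self.config.seed,
                "training_mode": self.config.training_mode,
            },
            "quantization_error": float(self.quantization_error),
            "qe_history": [float(q) for q in self.qe_history],
        }
        with open(outdir / "model.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)
        return outdir

    @classmethod
    def load(cls, indir: str | Path) -> "SOMModel":
        indir = Path(indir)
        with open(indir / "model.yaml") as fh:
            meta = yaml.safe_load(fh)
        config = SOMConfig(**meta["config"])
        codebook_df = pd.read_csv(indir / "codebook.tsv", sep="\t", index_col="unit_index")
        bmu_df = pd.read_csv(indir / "bmu.tsv", sep="\t", dtype={"gene_id": str})
        return cls(
            config=config,
            codebook=codebook_df.to_numpy(dtype=float),
            gene_ids=tuple(bmu_df["gene_id"]),
            sample_ids=tuple(codebook_df.columns),
            bmu=bmu_df["unit_index"].to_numpy(dtype=int),
            quantization_error=float(meta["quantization_error"]),
            qe_history=tuple(meta["qe_history"]),
        )


def _assign_bmu(X: np.ndarray, codebook: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """BMU per gene plus the distance to it; ties go to the lowest unit index."""
    d = cdist(X, codebook, metric="euclidean")
    bmu = d.argmin(axis=1)
    return bmu, d[np.arange(len(X)), bmu]


def train(matrix: ExpressionMatrix, config: SOMConfig) -> SOMModel:
    """Train the map on a centered log-scale expression matrix.

    Batch mode: each epoch assigns every gene to its BMU, then every prototype
    becomes the Gaussian-neighborhood-weighted mean of the gene profiles
    collected per unit. The final BMU assignment is recomputed against the
    final codebook, so BMU optimality holds exactly by construction.
    """
    if matrix.scale != "log10-qnorm-centered":
        raise PipelineOrderError(
            f"train expects a matrix on scale 'log10-qnorm-centered', got '{matrix.scale}'"
        )
    X = matrix.values
    if np.isnan(X).any():
        raise ValueError("input matrix contains NaN")
    if not X.any():
        warnings.warn("training on an all-zero matrix")

    codebook = initialize_codebook(matrix, config).astype(float)
    coords = _lattice_coords(config.rows, config.cols)
    # squared lattice distances between units; fixed across epochs
    unit_d2 = cdist(coords, coords, metric="sqeuclidean")

    qe_history: list[float] = []
    if config.training_mode == "batch":
        for epoch in range(config.n_epochs):
            radius = config.radius_at(epoch)
            bmu, dist = _assign_bmu(X, codebook)
            qe_history.append(float(dist.mean()))
            kernel = np.exp(-unit_d2 / (2.0 * radius * radius))
            sums = np.zeros_like(codebook)
            np.add.at(sums, bmu, X)
            counts = np.bincount(bmu, minlength=config.n_units).astype(float)
            denom = kernel @ counts
            codebook = (kernel @ sums) / denom[:, None]
    else:  # online
        rng = np.random.default_rng(config.seed)
        lr0, lr1 = 0.5, 0.01
        for epoch in range(config.n_epochs):
            radius = config.radius_at(epoch)
            frac = epoch / max(config.n_epochs - 1, 1)
            lr = lr0 * (lr1 / lr0) ** frac
            kernel_cache = np.exp(-unit_d2 / (2.0 * radius * radius))
            order = rng.permutation(len(X))
            for g in order:
                x = X[g]
                d = ((codebook - x) ** 2).sum(axis=1)
                unit = int(d.argmin())
                codebook += (lr * kernel_cache[unit])[:, None] * (x - codebook)
            _, dist = _assign_bmu(X, codebook)
            qe_history.append(float(dist.mean()))

    tail = max(1, int(np.ceil(config.n_epochs * 0.1)))
    if tail > 1 and np.any(np.diff(qe_history[-tail:]) > 1e-9):
        warnings.warn("quantization error increased during the final training epochs")

    bmu, dist = _assign_bmu(X, codebook)
    return SOMModel(
        config=config,
        codebook=codebook,
        gene_ids=tuple(str(g) for g in matrix.gene_ids),
        sample_ids=tuple(str(s) for s in matrix.sample_ids),
        bmu=bmu,
        quantization_error=float(dist.mean()),
        qe_history=tuple(qe_history),
    )
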