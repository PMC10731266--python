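"""Synthetic condition-series expression data with planted co-expression modules.

The generator emulates a multi-cultivar temperature experiment: five grapevine
cultivars, four ordered temperature conditions (warm 21 °C, acclim 4 °C,
accfreeze 4→−3 °C, freeze −3 °C), up to three replicates per cell, and one
dropped replicate so the default design yields 59 samples. On the log10 scale
each gene has a log-normal baseline, a condition-specific mean shift if it
belongs to a planted module, a small cultivar offset, a shared latent factor
per module inducing within-module correlation, and independent replicate
noise. CPM-like values are the back-transform ``10**log10_value`` and are
therefore strictly positive.

Transition-state outlier samples are convex mixtures of two condition mean
signatures on the log scale, emulating samples caught between treatments.
Ground truth (module membership, planted sets, outlier weights) is exported
for recovery benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = [
    "StudyDesign",
    "PlantedModule",
    "PlantedSet",
    "OutlierSpec",
    "GeneratorConfig",
    "ConfigurationError",
    "generate_expression",
    "module_gene_ids",
    "gene_sets",
    "ground_truth",
    "write_ground_truth",
    "write_gmt",
]

DEFAULT_CULTIVARS = ("CabFra", "Chard", "Riesl", "Sangio", "Tocai")
DEFAULT_CONDITIONS = ("warm", "acclim", "accfreeze", "freeze")


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class StudyDesign:
    """Cultivar × condition × replicate layout of the experiment.

    The default reproduces the study design: 5 cultivars × 4 conditions ×
    3 replicates minus one dropped Riesling replicate = 59 samples.
    """

    cultivars: tuple[str, ...] = DEFAULT_CULTIVARS
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates_per_cell: int = 3
    dropped_samples: tuple[tuple[str, str, int], ...] = (("Riesl", "freeze", 3),)

    def __post_init__(self) -> None:
        if len(set(self.cultivars)) != len(self.cultivars):
            raise ConfigurationError("cultivar labels must be unique")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("condition labels must be unique")
        if self.replicates_per_cell < 1:
            raise ConfigurationError("replicates_per_cell must be >= 1")
        for cultivar, condition, rep in self.dropped_samples:
            if cultivar not in self.cultivars or condition not in self.conditions:
                raise ConfigurationError(f"dropped sample ({cultivar}, {condition}, {rep}) "
                                         "does not match the design")
            if not 1 <= rep <= self.replicates_per_cell:
                raise ConfigurationError(f"dropped replicate index {rep} out of range")

    @property
    def n_samples(self) -> int:
        full = len(self.cultivars) * len(self.conditions) * self.replicates_per_cell
        return full - len(set(self.dropped_samples))

    def sample_sheet(self) -> pd.DataFrame:
        """One row per retained sample: sample_id, cultivar, condition, replicate."""
        dropped = set(self.dropped_samples)
        rows = []
        for cultivar in self.cultivars:
            for condition in self.conditions:
                for rep in range(1, self.replicates_per_cell + 1):
                    if (cultivar, condition, rep) in dropped:
                        continue
                    rows.append(
                        (f"{cultivar}_{condition}_r{rep}", cultivar, condition, rep)
                    )
        return pd.DataFrame(rows, columns=["sample_id", "cultivar", "condition", "replicate"])

    def sample_ids(self) -> list[str]:
        return self.sample_sheet()["sample_id"].tolist()


@dataclass(frozen=True)
class PlantedModule:
    """A condition-specific co-expression module planted into the matrix."""

    module_id: str
    condition: str
    n_genes: int
    effect_size: float = 1.0  # log10-scale mean shift in the target condition
    within_module_correlation: float = 0.35

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ConfigurationError(f"module '{self.module_id}' needs n_genes >= 2")
        if not np.isfinite(self.effect_size):
            raise ConfigurationError(f"module '{self.module_id}' effect_size must be finite")
        if not 0.0 <= self.within_module_correlation < 1.0:
            raise ConfigurationError(
                f"module '{self.module_id}' within_module_correlation must be in [0, 1)"
            )


@dataclass(frozen=True)
class PlantedSet:
    """A named gene set drawn from the head of one planted module."""

    name: str
    module_id: str
    n_genes: int = 22


@dataclass(frozen=True)
class OutlierSpec:
    """A sample whose expected log profile mixes two condition signatures.

    ``weight`` is the share of the foreign condition ``mix_condition``;
    weight 0 leaves the sample on its nominal condition, weight 1 makes it a
    pure sample of the foreign condition.
    """

    cultivar: str
    condition: str
    replicate: int
    mix_condition: str
    weight: float

    @property
    def sample_id(self) -> str:
        return f"{self.cultivar}_{self.condition}_r{self.replicate}"


def _default_modules() -> tuple[PlantedModule, ...]:
    # 130 genes ≈ 2.6% of the default 5,000: a module's lattice footprint then
    # matches the 2% overexpression-quantile area of the default 40×40 map
    return tuple(
        PlantedModule(module_id=f"M_{condition}", condition=condition, n_genes=130)
        for condition in DEFAULT_CONDITIONS
    )


def _default_outliers() -> tuple[OutlierSpec, ...]:
    # Two chill-shock samples caught in transition toward the acclimated state
    # and one freeze sample resembling the warm controls.
    return (
        OutlierSpec("Riesl", "accfreeze", 1, "acclim", 0.7),
        OutlierSpec("Riesl", "accfreeze", 3, "acclim", 0.7),
        OutlierSpec("Tocai", "freeze", 1, "warm", 0.7),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-data generator; one master seed."""

    n_genes: int = 5000
    baseline_log_mean: float = 1.5
    baseline_log_sd: float = 0.8
    noise_sd: float = 0.25
    cultivar_sd: float = 0.05
    planted_modules: tuple[PlantedModule, ...] = field(default_factory=_default_modules)
    planted_sets: tuple[PlantedSet, ...] = (PlantedSet("thiamine_like", "M_acclim", 22),)
    n_decoy_sets: int = 30
    decoy_set_size: int = 22
    outlier_specs: tuple[OutlierSpec, ...] = field(default_factory=_default_outliers)
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.noise_sd < 0 or self.cultivar_sd < 0:
            raise ConfigurationError("noise_sd and cultivar_sd must be non-negative")
        ids = [m.module_id for m in self.planted_modules]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("module_id labels must be unique")
        total = sum(m.n_genes for m in self.planted_modules)
        if total > self.n_genes:
            raise ConfigurationError(
                f"planted modules need {total} genes but n_genes is {self.n_genes}"
            )
        modules = {m.module_id: m for m in self.planted_modules}
        for planted_set in self.planted_sets:
            if planted_set.module_id not in modules:
                raise ConfigurationError(
                    f"planted set '{planted_set.name}' references unknown module "
                    f"'{planted_set.module_id}'"
                )
            if planted_set.n_genes > modules[planted_set.module_id].n_genes:
                raise ConfigurationError(
                    f"planted set '{planted_set.name}' is larger than its module"
                )
        for spec in self.outlier_specs:
            if not 0.0 <= spec.weight <= 1.0:
                raise ConfigurationError(
                    f"outlier {spec.sample_id}: mixing weight must be in [0, 1]"
                )


def _validate_against_design(config: GeneratorConfig, design: StudyDesign) -> None:
    for module in config.planted_modules:
        if module.condition not in design.conditions:
            raise ConfigurationError(
                f"module '{module.module_id}' targets unknown condition '{module.condition}'"
            )
    sample_ids = set(design.sample_ids())
    for spec in config.outlier_specs:
        if spec.sample_id not in sample_ids:
            raise ConfigurationError(f"outlier sample '{spec.sample_id}' not in the design")
        if spec.mix_condition not in design.conditions:
            raise ConfigurationError(
                f"outlier '{spec.sample_id}' mixes toward unknown condition "
                f"'{spec.mix_condition}'"
            )


def _gene_id(i: int) -> str:
    return f"g{i:05d}"


def module_gene_ids(config: GeneratorConfig) -> dict[str, list[str]]:
    """Deterministic gene block per module: modules take consecutive gene IDs."""
    out: dict[str, list[str]] = {}
    start = 0
    for module in config.planted_modules:
        out[module.module_id] = [_gene_id(i) for i in range(start, start + module.n_genes)]
        start += module.n_genes
    return out


def gene_sets(config: GeneratorConfig) -> dict[str, list[str]]:
    """Planted sets plus seeded decoy sets, as name → member gene IDs."""
    blocks = module_gene_ids(config)
    sets: dict[str, list[str]] = {
        ps.name: blocks[ps.module_id][: ps.n_genes] for ps in config.planted_sets
    }
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    all_genes = np.array([_gene_id(i) for i in range(config.n_genes)])
    size = min(config.decoy_set_size, config.n_genes)
    for k in range(config.n_decoy_sets):
        members = rng.choice(all_genes, size=size, replace=False)
        sets[f"decoy_{k + 1:02d}"] = sorted(members.tolist())
    return sets


def generate_expression(
    config: GeneratorConfig, design: StudyDesign | None = None
) -> ExpressionMatrix:
    """Draw a CPM-like genes × samples matrix under the configured model.

    Same ``(config, design)`` (the seed lives in the config) gives a
    bit-identical matrix. Module genes get ``effect_size`` added to their
    log10 mean in exactly their target condition's samples; outlier samples
    receive the convex mixture of their two condition signatures.
    """
    design = design or StudyDesign()
    _validate_against_design(config, design)
    sheet = design.sample_sheet()
    n_genes, n_samples = config.n_genes, len(sheet)
    n_conditions = len(design.conditions)

    seeds = np.random.SeedSequence(config.seed).spawn(5)
    rng_baseline = np.random.default_rng(seeds[0])
    rng_cultivar = np.random.default_rng(seeds[1])
    rng_factor = np.random.default_rng(seeds[2])
    rng_noise = np.random.default_rng(seeds[3])

    gene_ids = [_gene_id(i) for i in range(n_genes)]
    baseline = rng_baseline.normal(config.baseline_log_mean, config.baseline_log_sd, n_genes)

    # condition effects: genes × conditions
    cond_index = {c: i for i, c in enumerate(design.conditions)}
    effects = np.zeros((n_genes, n_conditions))
    blocks = module_gene_ids(config)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for module in config.planted_modules:
        rows = [gene_pos[g] for g in blocks[module.module_id]]
        effects[rows, cond_index[module.condition]] += module.effect_size

    # condition weights per sample: one-hot, except convex mixtures for outliers
    weights = np.zeros((n_conditions, n_samples))
    outlier_by_id = {spec.sample_id: spec for spec in config.outlier_specs}
    for j, row in sheet.iterrows():
        spec = outlier_by_id.get(row.sample_id)
        if spec is None:
            weights[cond_index[row.condition], j] = 1.0
        else:
            weights[cond_index[row.condition], j] = 1.0 - spec.weight
            weights[cond_index[spec.mix_condition], j] += spec.weight

    log_expr = baseline[:, None] + effects @ weights

    # cultivar offsets: independent per gene × cultivar
    offsets = rng_cultivar.normal(0.0, config.cultivar_sd, (n_genes, len(design.cultivars)))
    cultivar_index = {c: i for i, c in enumerate(design.cultivars)}
    log_expr += offsets[:, [cultivar_index[c] for c in sheet["cultivar"]]]

    # shared latent factor per module: induces within-module correlation r by
    # splitting the replicate noise variance into r (shared) + (1-r) (private)
    noise_scale = np.full(n_genes, config.noise_sd)
    for module in config.planted_modules:
        rows = [gene_pos[g] for g in blocks[module.module_id]]
        r = module.within_module_correlation
        factor = rng_factor.normal(0.0, config.noise_sd * np.sqrt(r), n_samples)
        log_expr[rows, :] += factor[None, :]
        noise_scale[rows] = config.noise_sd * np.sqrt(1.0 - r)

    log_expr += rng_noise.normal(0.0, 1.0, (n_genes, n_samples)) * noise_scale[:, None]

    df = pd.DataFrame(
        np.power(10.0, log_expr), index=pd.Index(gene_ids, name="gene_id"),
        columns=sheet["sample_id"].tolist(),
    )
    return ExpressionMatrix(df, scale="cpm")


# ---------------------------------------------------------------------------
# Ground truth export
# ---------------------------------------------------------------------------

def ground_truth(
    config: GeneratorConfig, design: StudyDesign | None = None
) -> dict[str, pd.DataFrame]:
    """Machine-readable truth tables for recovery benchmarks."""
    design = design or StudyDesign()
    _validate_against_design(config, design)
    blocks = module_gene_ids(config)

    gene_rows = [
        (gene, module.module_id)
        for module in config.planted_modules
        for gene in blocks[module.module_id]
    ]
    module_rows = [
        (m.module_id, m.condition, m.n_genes, m.effect_size, m.within_module_correlation)
        for m in config.planted_modules
    ]
    set_rows = [
        (ps.name, gene)
        for ps in config.planted_sets
        for gene in blocks[ps.module_id][: ps.n_genes]
    ]
    outlier_rows = [
        (spec.sample_id, spec.condition, spec.mix_condition, spec.weight)
        for spec in config.outlier_specs
    ]
    return {
        "gene_modules": pd.DataFrame(gene_rows, columns=["gene_id", "module_id"]),
        "modules": pd.DataFrame(
            module_rows,
            columns=["module_id", "condition", "n_genes", "effect_size", "correlation"],
        ),
        "set_members": pd.DataFrame(set_rows, columns=["set_name", "gene_id"]),
        "outliers": pd.DataFrame(
            outlier_rows, columns=["sample_id", "condition", "mix_condition", "weight"]
        ),
    }


def write_gmt(sets: dict[str, Sequence[str]], path: str | Path, description: str = "") -> Path:
    """Write gene sets in GMT format (name, description, members; tab-separated)."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description or name, *members]) + "\n")
    return path


def write_ground_truth(
    config: GeneratorConfig, outdir: str | Path, design: StudyDesign | None = None
) -> dict[str, Path]:
    """Write truth tables as TSV plus the planted/decoy sets as GMT."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, frame in ground_truth(config, design).items():
        paths[name] = outdir / f"{name}.tsv"
        frame.to_csv(paths[name], sep="\t", index=False)
    paths["gene_sets_gmt"] = write_gmt(gene_sets(config), outdir / "gene_sets.gmt")
    return paths
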