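"""End-to-end orchestration: one config, one seed, one output directory.

A run goes synthetic-generation (or file loading with optional gene-ID
conversion) → normalization → SOM training → portraits → spot catalog →
spot network → sample tree and clade report → gene-set statistics, writing
every artifact as plain text (TSV/GMT/newick/YAML) plus portrait PNGs, and
returns a machine-readable report whose stage counts satisfy conservation
identities. Identical config + seed reproduces identical TSV artifacts.
"""

from __future__ import annotations

import dataclasses
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    GeneSet,
    enrich_all,
    read_gmt,
    setcount_per_spot,
    top_genes,
    top_sets_per_spot,
    zscore_table,
)
from .portraits import (
    condition_portraits,
    gene_spot_frame,
    group_spot_summary,
    render_portraits,
    sample_portrait,
    spot_catalog_frame,
    spot_profiles,
    unassigned_genes,
    wto_network,
)
from .preprocess import (
    ConversionReport,
    ExpressionMatrix,
    GeneIDMap,
    load_expression,
    load_id_map_from_gff3,
    load_id_map_from_tsv,
    normalize_for_som,
    read_sample_sheet,
)
from .simulate import (
    GeneratorConfig,
    StudyDesign,
    gene_sets as synthetic_gene_sets,
    generate_expression,
    write_ground_truth,
)
from .som import SOMConfig, train
from .trees import condition_clades, neighbor_joining, profile_distances, sample_distances

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_config", "load_run_config"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs; exactly one input mode.

    Synthetic mode uses ``generator`` + ``design``; file mode uses
    ``expression_path`` + ``sample_sheet_path`` (+ optional ID map). The
    master ``seed`` overrides the generator and SOM seeds so one integer
    pins the whole run.
    """

    outdir: str = "somportrait_run"
    seed: int = 17
    force: bool = False

    # input: synthetic …
    synthetic: bool = True
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    design: StudyDesign = field(default_factory=StudyDesign)
    # … or files
    expression_path: str | None = None
    sample_sheet_path: str | None = None
    id_map_path: str | None = None  # two-column TSV
    gff3_path: str | None = None
    gff3_old_key: str = "ID"
    gff3_new_key: str = "Name"

    pseudocount: float = 1.0
    som: SOMConfig = field(default_factory=SOMConfig)
    threshold_quantile: float = 0.98
    min_units: int = 4
    tree_metric: str = "correlation"
    tree_space: str = "metagene"  # or "gene"
    clade_jaccard: float = 0.5
    gmt_paths: tuple[str, ...] = ()
    top_k_sets: int = 3
    top_k_genes: int = 20
    render_sample_portraits: bool = False

    def validate(self) -> list[str]:
        """All violations at once (empty list means the config is runnable)."""
        errors: list[str] = []
        file_mode = self.expression_path is not None
        if self.synthetic and file_mode:
            errors.append("both input modes set: synthetic=true and expression_path given")
        if not self.synthetic and not file_mode:
            errors.append("no input mode: set synthetic=true or provide expression_path")
        if file_mode:
            for name in ("expression_path", "sample_sheet_path", "id_map_path", "gff3_path"):
                value = getattr(self, name)
                if value is not None and not Path(value).exists():
                    errors.append(f"{name}: file not found: {value}")
            if self.sample_sheet_path is None:
                errors.append("file input mode requires sample_sheet_path")
        for path in self.gmt_paths:
            if not Path(path).exists():
                errors.append(f"gmt path not found: {path}")
        if self.som.rows < 1 or self.som.cols < 1:
            errors.append("SOMConfig.rows and SOMConfig.cols must be >= 1")
        if not 0 < self.threshold_quantile < 1:
            errors.append("threshold_quantile must be in (0, 1)")
        if self.min_units < 1:
            errors.append("min_units must be >= 1")
        if self.tree_metric not in ("correlation", "euclidean"):
            errors.append(f"unknown tree_metric '{self.tree_metric}'")
        if self.tree_space not in ("metagene", "gene"):
            errors.append(f"unknown tree_space '{self.tree_space}'")
        if self.pseudocount <= 0:
            errors.append("pseudocount must be positive")
        return errors


@dataclass
class RunReport:
    """Stage counts, config echo and timings of one pipeline run."""

    version: str
    seed: int
    n_genes_loaded: int = 0
    n_genes_dropped: int = 0
    n_genes_trained: int = 0
    n_samples: int = 0
    n_spots: int = 0
    spot_sizes: dict[str, int] = field(default_factory=dict)
    n_genes_in_spots: int = 0
    n_genes_unassigned: int = 0
    n_enrichment_tests: int = 0
    n_major_clades: int = 0
    outgrouped_samples: tuple[str, ...] = ()
    quantization_error: float = float("nan")
    stage_seconds: dict[str, float] = field(default_factory=dict)
    config: dict[str, Any] = field(default_factory=dict)

    def check_conservation(self) -> None:
        """Loaded = trained + dropped; spot genes + unassigned = trained."""
        if self.n_genes_loaded != self.n_genes_trained + self.n_genes_dropped:
            raise AssertionError("gene conservation violated: loaded != trained + dropped")
        if self.n_genes_in_spots + self.n_genes_unassigned != self.n_genes_trained:
            raise AssertionError("spot gene conservation violated")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        payload["outgrouped_samples"] = list(self.outgrouped_samples)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
        return path


def _config_echo(config: RunConfig) -> dict[str, Any]:
    def unwrap(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: unwrap(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [unwrap(o) for o in obj]
        return obj

    return unwrap(config)


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full workflow; see the module docstring for the stages."""
    errors = config.validate()
    if errors:
        raise ValueError("invalid run config:\n" + "\n".join(f"  - {e}" for e in errors))

    outdir = Path(config.outdir)
    if outdir.exists() and any(outdir.iterdir()) and not config.force:
        raise FileExistsError(f"output directory {outdir} is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)

    report = RunReport(version=__version__, seed=config.seed, config=_config_echo(config))
    clock = time.perf_counter
    t0 = clock()

    # ------------------------------------------------------------------ input
    sets: list[GeneSet] = []
    if config.synthetic:
        generator = dataclasses.replace(config.generator, seed=config.seed)
        matrix = generate_expression(generator, config.design)
        sheet = config.design.sample_sheet()
        matrix.to_tsv(outdir / "expression.tsv")
        _write_tsv(sheet, outdir / "samples.tsv")
        write_ground_truth(generator, outdir / "truth", config.design)
        sets = [
            GeneSet(name, frozenset(members))
            for name, members in synthetic_gene_sets(generator).items()
        ]
        report.n_genes_dropped = 0
    else:
        matrix = load_expression(config.expression_path)
        sheet = read_sample_sheet(config.sample_sheet_path)
        idmap: GeneIDMap | None = None
        if config.gff3_path:
            idmap = load_id_map_from_gff3(
                config.gff3_path, config.gff3_old_key, config.gff3_new_key
            )
        elif config.id_map_path:
            idmap = load_id_map_from_tsv(config.id_map_path)
        if idmap is not None:
            from .preprocess import convert_and_filter

            n_before = matrix.n_genes
            matrix, conv = convert_and_filter(matrix, idmap)
            report.n_genes_dropped = conv.n_dropped
            _write_tsv(conv.to_frame(), outdir / "conversion_report.tsv")
    for path in config.gmt_paths:
        sets.extend(read_gmt(path))

    report.n_genes_loaded = matrix.n_genes + report.n_genes_dropped
    report.n_samples = matrix.n_samples
    report.stage_seconds["input"] = clock() - t0

    # ------------------------------------------------------------- preprocess
    t0 = clock()
    normalized = normalize_for_som(matrix, config.pseudocount)
    normalized.to_tsv(outdir / "normalized.tsv")
    report.stage_seconds["preprocess"] = clock() - t0

    # ------------------------------------------------------------------ train
    t0 = clock()
    som_config = dataclasses.replace(config.som, seed=(config.seed + 1) % (2**31))
    model = train(normalized, som_config)
    model.save(outdir / "model")
    report.n_genes_trained = len(model.gene_ids)
    report.quantization_error = model.quantization_error
    report.stage_seconds["train"] = clock() - t0

    # -------------------------------------------------------------- portraits
    t0 = clock()
    groups = {
        condition: grp["sample_id"].tolist()
        for condition, grp in sheet.groupby("condition", sort=False)
    }
    group_portraits = condition_portraits(model, groups)
    render_portraits(list(group_portraits.values()), outdir / "portraits", shared_scale=True)
    if config.render_sample_portraits:
        render_portraits(
            [sample_portrait(model, s) for s in model.sample_ids],
            outdir / "portraits" / "samples",
            shared_scale=True,
        )
    report.stage_seconds["portraits"] = clock() - t0

    # ------------------------------------------------------------------ spots
    t0 = clock()
    catalog = group_spot_summary(model, groups, config.threshold_quantile, config.min_units)
    _write_tsv(spot_catalog_frame(catalog), outdir / "spot_catalog.tsv")
    _write_tsv(gene_spot_frame(catalog), outdir / "gene_spots.tsv")
    profiles = spot_profiles(model, catalog)
    profiles.to_csv(outdir / "spot_profiles.tsv", sep="\t",
                    index_label="spot", float_format="%.10g")
    if len(catalog) >= 2:
        network = wto_network(profiles)
        network.wto.to_csv(outdir / "spot_wto.tsv", sep="\t",
                           index_label="spot", float_format="%.10g")
        network.correlation.to_csv(outdir / "spot_correlation.tsv", sep="\t",
                                   index_label="spot", float_format="%.10g")
    report.n_spots = len(catalog)
    report.spot_sizes = {s.label: s.n_genes for s in catalog}
    report.n_genes_in_spots = sum(s.n_genes for s in catalog)
    report.n_genes_unassigned = len(unassigned_genes(model, catalog))
    report.stage_seconds["spots"] = clock() - t0

    # ------------------------------------------------------------------- tree
    t0 = clock()
    if config.tree_space == "metagene":
        dist = sample_distances(model, config.tree_metric)
    else:
        dist = profile_distances(normalized.df, config.tree_metric)
    pd.DataFrame(dist.data, index=list(dist.ids), columns=list(dist.ids)).to_csv(
        outdir / "sample_distances.tsv", sep="\t", index_label="sample_id",
        float_format="%.10g",
    )
    tree = neighbor_joining(dist)
    tree.write(str(outdir / "sample_tree.nwk"))
    clades = condition_clades(tree, sheet, config.clade_jaccard)
    _write_tsv(clades.per_condition, outdir / "clade_report.tsv")
    report.n_major_clades = clades.n_major_clades
    report.outgrouped_samples = clades.outgrouped
    report.stage_seconds["tree"] = clock() - t0

    # ------------------------------------------------------------- enrichment
    t0 = clock()
    if sets and catalog:
        universe = list(model.gene_ids)
        testable = [s for s in sets if any(g in s.members for g in universe)]
        enrichment = enrich_all(catalog, testable, universe)
        _write_tsv(enrichment, outdir / "enrichment.tsv")
        _write_tsv(top_sets_per_spot(enrichment, config.top_k_sets),
                   outdir / "enrichment_top.tsv")
        zscores = zscore_table(normalized, testable)
        zscores.to_csv(outdir / "set_zscores.tsv", sep="\t",
                       index_label="set", float_format="%.10g")
        counts = pd.DataFrame({gs.name: setcount_per_spot(catalog, gs) for gs in testable})
        counts.to_csv(outdir / "set_counts_per_spot.tsv", sep="\t", index_label="spot")
        report.n_enrichment_tests = len(enrichment)
    if catalog:
        tops = []
        for spot in catalog:
            group = spot.source_portrait.split("+")[0]
            ranked = top_genes(spot, normalized, groups[group], config.top_k_genes)
            ranked.insert(0, "spot", spot.label)
            tops.append(ranked)
        _write_tsv(pd.concat(tops, ignore_index=True), outdir / "top_genes.tsv")
    report.stage_seconds["enrichment"] = clock() - t0

    report.check_conservation()
    report.to_yaml(outdir / "run_report.yaml")
    return report


# ---------------------------------------------------------------------------
# YAML config loading / validation
# ---------------------------------------------------------------------------

def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (missing keys take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    from .simulate import OutlierSpec, PlantedModule, PlantedSet

    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key == "generator":
            value = dict(value)
            if "planted_modules" in value:
                value["planted_modules"] = tuple(
                    PlantedModule(**m) for m in value["planted_modules"]
                )
            if "planted_sets" in value:
                value["planted_sets"] = tuple(PlantedSet(**s) for s in value["planted_sets"])
            if "outlier_specs" in value:
                value["outlier_specs"] = tuple(OutlierSpec(**o) for o in value["outlier_specs"])
            kwargs[key] = GeneratorConfig(**value)
        elif key == "design":
            value = dict(value)
            for field_name in ("cultivars", "conditions"):
                if field_name in value:
                    value[field_name] = tuple(value[field_name])
            if "dropped_samples" in value:
                value["dropped_samples"] = tuple(tuple(d) for d in value["dropped_samples"])
            kwargs[key] = StudyDesign(**value)
        elif key == "som":
            kwargs[key] = SOMConfig(**value)
        elif key == "gmt_paths":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def validate_config(path: str | Path) -> list[str]:
    """Parse + validate a YAML config; returns all violations at once."""
    try:
        config = load_run_config(path)
    except Exception as exc:
        return [f"config does not parse: {exc}"]
    return config.validate()
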