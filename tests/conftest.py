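"""Shared fixtures: small synthetic datasets and tiny trained maps."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from somportrait.preprocess import ExpressionMatrix, normalize_for_som
from somportrait.simulate import (
    GeneratorConfig,
    OutlierSpec,
    PlantedModule,
    PlantedSet,
    StudyDesign,
    generate_expression,
)
from somportrait.som import SOMConfig, train


def centered(values, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    """Wrap a 2-D array as a centered-scale matrix (for direct SOM input)."""
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        scale="log10-qnorm-centered",
    )


def small_generator(seed: int = 7, n_genes: int = 600) -> GeneratorConfig:
    """Scaled-down generator: 25-gene module per condition, fewer decoys."""
    modules = tuple(
        PlantedModule(f"M_{c}", c, 25) for c in ("warm", "acclim", "accfreeze", "freeze")
    )
    return GeneratorConfig(
        n_genes=n_genes,
        planted_modules=modules,
        planted_sets=(PlantedSet("planted_set", "M_acclim", 10),),
        n_decoy_sets=5,
        decoy_set_size=10,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_run():
    """A small but complete trained run shared by several test modules.

    600 genes, 59 samples, 16×16 map; planted 25-gene module per condition.
    """
    config = small_generator(seed=7)
    design = StudyDesign()
    matrix = generate_expression(config, design)
    normalized = normalize_for_som(matrix)
    model = train(normalized, SOMConfig(rows=16, cols=16, n_epochs=25, seed=8))
    sheet = design.sample_sheet()
    return {
        "config": config,
        "design": design,
        "matrix": matrix,
        "normalized": normalized,
        "model": model,
        "sheet": sheet,
        "groups": {
            c: g["sample_id"].tolist() for c, g in sheet.groupby("condition", sort=False)
        },
    }
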