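import numpy as np
import pandas as pd
import pytest

from agemeta.io import (
    DatasetMetadata,
    DifferentialExpressionTable,
    GeneSet,
    GeneSetCatalogue,
)


def make_table(dataset_id, log2fc, pvalues=None, genes=None):
    """Build a DE table from plain sequences."""
    log2fc = np.asarray(log2fc, dtype=float)
    if genes is None:
        genes = [f"g{i:04d}" for i in range(len(log2fc))]
    if pvalues is None:
        pvalues = np.full(len(log2fc), 0.5)
    return DifferentialExpressionTable(
        dataset_id=dataset_id,
        data=pd.DataFrame({"gene_id": list(genes), "log2fc": log2fc,
                           "pvalue": np.asarray(pvalues, dtype=float)}),
    )


def make_metadata(dataset_id, intervention, study=None, group="long", tissue="liver"):
    return DatasetMetadata(
        dataset_id=dataset_id,
        study_id=study or f"{intervention}_st1",
        intervention_id=intervention,
        tissue=tissue,
        lifespan_effect=group,
    )


@pytest.fixture
def tiny_catalogue():
    return GeneSetCatalogue([
        GeneSet("T1", "first", frozenset({"g1", "g2", "g3"})),
        GeneSet("T2", "second", frozenset({"g3", "g4", "g5", "g6"})),
        GeneSet("T3", "third", frozenset({"g7", "g8"})),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
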