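from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from omeconcord.io_model import (
    AbundanceMatrix,
    DifferentialRecord,
    DifferentialTable,
    EnrichmentConfig,
    FeatureUniverse,
    PeptideTable,
)


@pytest.fixture
def small_universe() -> FeatureUniverse:
    """20 features, one 5-member term — matches hand-enumerable tail sums."""
    features = [f"g{i}" for i in range(20)]
    return FeatureUniverse(
        features=frozenset(features),
        terms={"T1": ("term one", frozenset(features[:5]))},
        namespace="custom",
        kind="gene",
    )


@pytest.fixture
def cfg() -> EnrichmentConfig:
    return EnrichmentConfig()


def make_table(
    sde: dict[str, float], tissue: str, ome: str = "transcriptome",
    universe_features: list[str] | None = None,
) -> DifferentialTable:
    """Build a differential table from feature -> signed log2fc for SDE
    features; remaining universe features are emitted as non-significant."""
    records = [
        DifferentialRecord(f, lfc, 0.001, 0.001, tissue=tissue, ome=ome)
        for f, lfc in sde.items()
    ]
    for f in universe_features or []:
        if f not in sde:
            records.append(
                DifferentialRecord(f, 0.1, 0.5, 0.5, tissue=tissue, ome=ome)
            )
    return DifferentialTable(records, tissue=tissue, ome=ome)


@pytest.fixture
def tiny_matrix() -> AbundanceMatrix:
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, np.nan, 6.0]],
        index=["D1", "R1"],
        columns=["m1", "m2", "m3"],
    )
    return AbundanceMatrix(values=values,
                           groups={"D1": "deficient", "R1": "replete"})


@pytest.fixture
def two_peptide_table() -> PeptideTable:
    samples = ["D1", "D2", "R1", "R2"]
    values = pd.DataFrame(
        {
            "P1_a": [10.0, 11.0, 12.0, 13.0],
            "P1_b": [8.0, 9.0, 10.0, 11.0],   # = P1_a - 2 everywhere
        },
        index=samples,
    ).T
    return PeptideTable(
        values=values,
        protein_of={"P1_a": "P1", "P1_b": "P1"},
        groups={"D1": "deficient", "D2": "deficient",
                "R1": "replete", "R2": "replete"},
    )
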