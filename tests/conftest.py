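from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from revtraj import ClassificationConfig, ExpressionMatrix, RatioTable

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def cc() -> ClassificationConfig:
    return ClassificationConfig()


@pytest.fixture
def gmt_path() -> Path:
    return DATA_DIR / "synthetic_kegg_sets.gmt"


def make_matrix(values, gene_ids=None, condition_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    condition_ids = condition_ids or [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=condition_ids))


def make_ratio_table(ratios, gene_ids=None, num="perturbed", den="baseline") -> RatioTable:
    ratios = np.asarray(ratios, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(len(ratios))]
    return RatioTable(
        gene_ids=tuple(gene_ids),
        numerator_condition=num,
        denominator_condition=den,
        ratio=ratios,
    )


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    return make_matrix(
        [[10.0, 5.0, 7.0], [0.0, 2.0, 1.0], [100.0, 40.0, 80.0]],
        gene_ids=["Actb", "Nanog", "Gapdh"],
        condition_ids=["MEF", "OKS", "OKS_T20"],
    )
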