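"""Shared fixtures: small random annotation matrices, queries and graphs."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ishatlas.annotation import AnnotationMatrix
from ishatlas.levels import ExpressionLevel

STATE_TOKENS = [lv.value for lv in ExpressionLevel]


def random_matrix(
    rng: np.random.Generator,
    n_genes: int = 20,
    tissues: tuple = ("T1", "T2", "T3", "T4"),
    p_states: tuple = (0.05, 0.45, 0.3, 0.15, 0.05),
) -> AnnotationMatrix:
    """Random matrix with i.i.d. cells over (na, neg, weak, medium, strong)."""
    genes = [f"g{i:03d}" for i in range(1, n_genes + 1)]
    cells = rng.choice(STATE_TOKENS, size=(n_genes, len(tissues)), p=p_states)
    return AnnotationMatrix(pd.DataFrame(cells, index=genes, columns=list(tissues)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def small_matrix(rng) -> AnnotationMatrix:
    return random_matrix(rng, n_genes=20)
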