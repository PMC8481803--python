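import numpy as np
import pandas as pd
import pytest

from trailkit.enrichment import RankedList
from trailkit.scoring import GroupAssignment
from trailkit.types import ExpressionMatrix, GeneSet, GeneSetCollection, ScoreList


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 genes x 6 samples, 3 per group, simple integer values."""
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.integers(1, 20, size=(4, 6)).astype(float),
        index=["g1", "g2", "g3", "g4"],
        columns=[f"s{i}" for i in range(1, 7)],
    )
    meta = pd.DataFrame({"group": ["A"] * 3 + ["B"] * 3}, index=values.columns)
    return ExpressionMatrix(values, meta, mode="normalized")


@pytest.fixture
def groups_ab(small_matrix) -> GroupAssignment:
    return GroupAssignment(
        {c: ("A" if i < 3 else "B") for i, c in enumerate(small_matrix.columns)}
    )


@pytest.fixture
def ranked_five() -> RankedList:
    return RankedList(
        ScoreList([("g1", 5.0), ("g2", 4.0), ("g3", 3.0), ("g4", 2.0), ("g5", 1.0)])
    )


@pytest.fixture
def one_set_collection() -> GeneSetCollection:
    return GeneSetCollection(
        [GeneSet("s1", "", frozenset({"G1", "G2", "G3"}))]
    )
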