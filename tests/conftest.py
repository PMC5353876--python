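import numpy as np
import pytest

from perturbnet import (
    ExpressionMatrix,
    InteractionSet,
    TimeGrouping,
)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        ("gA", "gB", "gC"),
        ("t1", "t2", "t3", "t4"),
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [4.0, 3.0, 2.0, 1.0],
                [2.5, 2.5, 2.5, 2.5],
            ]
        ),
    )


@pytest.fixture
def small_scaffold() -> InteractionSet:
    return InteractionSet.from_pairs([("gA", "gB"), ("gB", "gC"), ("gA", "gC")])


@pytest.fixture
def pair_grouping() -> TimeGrouping:
    return TimeGrouping((("early", ("t1", "t2")), ("late", ("t3", "t4"))))


def random_matrix(rng: np.random.Generator, n_genes: int, n_times: int) -> ExpressionMatrix:
    return ExpressionMatrix(
        tuple(f"g{i}" for i in range(n_genes)),
        tuple(f"t{j}" for j in range(n_times)),
        rng.normal(size=(n_genes, n_times)),
    )
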