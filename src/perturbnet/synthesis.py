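"""Synthetic datasets with a planted conserved, context-drifting module, plus
the small worked-example fixture used throughout the tests.

Module genes drift linearly from -amplitude to +amplitude (or the reverse)
across time points; background genes are baseline + i.i.d. Gaussian noise.
Baselines are drawn from a common distribution so quantile normalization is
near-neutral on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, InteractionSet, TimeGrouping, canonical_edge
from .network import CommonNetwork
from .perturbation import PerturbationMatrix, ThresholdSpec

_BASELINE_MEAN = 8.0
_BASELINE_SD = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 500
    n_timepoints: int = 8
    module_size: int = 10
    module_edges: int = 12
    amplitude: float = 5.0
    noise_sd: float = 1.0
    scaffold_edges: int = 300
    direction_split: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_timepoints < 2:
            raise ValueError("need >= 1 gene and >= 2 time points")
        if not 0 <= self.module_size <= self.n_genes:
            raise ValueError("module_size must be between 0 and n_genes")
        if self.module_edges > self.module_size * (self.module_size - 1) // 2:
            raise ValueError(
                f"{self.module_edges} module edges infeasible for {self.module_size} genes"
            )
        if self.scaffold_edges > self.n_genes * (self.n_genes - 1) // 2:
            raise ValueError(
                f"{self.scaffold_edges} scaffold edges infeasible for {self.n_genes} genes"
            )
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be nonnegative")
        if not 0.0 <= self.direction_split <= 1.0:
            raise ValueError("direction_split must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    module_genes: frozenset[str]
    module_edges: frozenset[tuple[str, str]]


def _sample_pairs(
    n: int, count: int, rng: np.random.Generator, labels: list[str]
) -> set[tuple[str, str]]:
    """Uniform without-replacement sample of `count` unordered pairs among n items."""
    total = n * (n - 1) // 2
    flat = rng.choice(total, size=count, replace=False)
    # invert the row-major upper-triangle linear index
    i = (n - 2 - np.floor(np.sqrt(-8 * flat + 4 * n * (n - 1) - 7) / 2.0 - 0.5)).astype(int)
    j = (flat + i + 1 - i * (2 * n - i - 1) // 2).astype(int)
    return {canonical_edge(labels[a], labels[b]) for a, b in zip(i, j)}


def simulate_dataset(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, InteractionSet, GroundTruth]:
    """Generate an expression matrix and an interaction scaffold containing a
    planted module whose genes drift monotonically across time points."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_genes, config.n_timepoints
    width = len(str(max(n - 1, 1)))
    genes = [f"G{i:0{width}d}" for i in range(n)]
    time_labels = tuple(f"t{j + 1}" for j in range(m))

    baseline = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=n)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n, m))

    module_idx = np.sort(rng.choice(n, size=config.module_size, replace=False))
    ramp = np.linspace(-config.amplitude, config.amplitude, m)
    n_up = int(round(config.direction_split * config.module_size))
    directions = np.array([1.0] * n_up + [-1.0] * (config.module_size - n_up))
    for i, d in zip(module_idx, directions):
        values[i, :] += d * ramp

    module_genes = frozenset(genes[i] for i in module_idx)
    module_labels = [genes[i] for i in module_idx]
    module_edges: set[tuple[str, str]] = set()
    if config.module_edges:
        module_edges = _sample_pairs(config.module_size, config.module_edges, rng, module_labels)
    background = _sample_pairs(n, config.scaffold_edges, rng, genes) if config.scaffold_edges else set()
    scaffold = InteractionSet(frozenset(module_edges | background))

    matrix = ExpressionMatrix(tuple(genes), time_labels, values)
    return matrix, scaffold, GroundTruth(module_genes, frozenset(module_edges))


def even_grouping(time_labels, n_stages: int) -> TimeGrouping:
    """Split an ordered label list into n_stages contiguous, near-equal stages."""
    time_labels = list(time_labels)
    if not 2 <= n_stages <= len(time_labels):
        raise ValueError(f"cannot split {len(time_labels)} time points into {n_stages} stages")
    bounds = np.linspace(0, len(time_labels), n_stages + 1).round().astype(int)
    stages = tuple(
        (f"stage{k + 1}", tuple(time_labels[bounds[k] : bounds[k + 1]]))
        for k in range(n_stages)
    )
    return TimeGrouping(stages)


@dataclass(frozen=True)
class WorkedExample:
    """Tiny hand-checkable fixture exercising every pipeline stage.

    ``expression`` holds one gene whose value at t2 is 0.2 and whose row mean
    is 0.45, so its t1/t2 scores are -0.15/-0.25 and its grouped score over
    {t1, t2} is -0.2 — inside the +/-0.376 band, hence a final score of 0.
    ``member_scores`` holds the two common-network members whose grouped
    scores (0.5 vs -0.45 and -0.775 vs 0.475) give an average absolute shift
    of 1.1 between the two stages.
    """

    expression: ExpressionMatrix
    grouping: TimeGrouping
    thresholds: ThresholdSpec
    member_scores: PerturbationMatrix
    common: CommonNetwork
    expected: dict = field(default_factory=dict)


def figure2_fixture() -> WorkedExample:
    expression = ExpressionMatrix(
        ("gene3",),
        ("t1", "t2", "t3", "t4"),
        np.array([[0.30, 0.20, 0.70, 0.60]]),  # mean 0.45
    )
    grouping = TimeGrouping((("t1and2", ("t1", "t2")), ("t3", ("t3",)), ("t4", ("t4",))))
    thresholds = ThresholdSpec(mu=0.0, sigma=0.376, k=1.0)
    member_scores = PerturbationMatrix(
        ("gene2", "gene4"),
        ("t1and2", "t4"),
        np.array([[0.5, -0.45], [-0.775, 0.475]]),
        grouped=True,
    )
    common = CommonNetwork(frozenset({canonical_edge("gene2", "gene4")}))
    expected = {
        "score_t2": -0.25,
        "grouped_score": -0.2,
        "final_score": 0.0,
        "delta_p": 1.1,
        "lower": -0.376,
        "upper": 0.376,
    }
    return WorkedExample(expression, grouping, thresholds, member_scores, common, expected)
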