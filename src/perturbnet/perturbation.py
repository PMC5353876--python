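"""Perturbation scoring: per-gene deviation from the across-time mean,
stage grouping, the pooled mean +/- k*sd threshold, and selection of
perturbed gene sets.

The score of gene i at time point j is its expression value minus the mean
of its expression over all time points; by construction each gene's
ungrouped scores sum to zero.  Grouped scores are arithmetic means over a
stage's raw time points.  A gene's final score at a stage is its grouped
score if it falls strictly outside the pooled mean +/- k*sd band, else 0;
genes with a nonzero final score form that stage's perturbed set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, TimeGrouping


@dataclass(frozen=True, eq=False)
class PerturbationMatrix:
    """Gene x (time point or stage) perturbation scores."""

    gene_ids: tuple[str, ...]
    stage_labels: tuple[str, ...]
    scores: np.ndarray
    grouped: bool = False

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "stage_labels", tuple(self.stage_labels))
        if scores.shape != (len(self.gene_ids), len(self.stage_labels)):
            raise ValueError(
                f"scores shape {scores.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.stage_labels)} stages"
            )

    def stage_index(self, label: str) -> int:
        try:
            return self.stage_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown stage label {label!r}") from None

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PerturbationMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.stage_labels == other.stage_labels
            and self.grouped == other.grouped
            and np.array_equal(self.scores, other.scores)
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class ThresholdSpec:
    """Symmetric selection band mu +/- k*sigma on pooled scores."""

    mu: float
    sigma: float
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if not self.lower < self.upper:
            raise ValueError("degenerate threshold band (sigma*k == 0)")

    @property
    def lower(self) -> float:
        return self.mu - self.k * self.sigma

    @property
    def upper(self) -> float:
        return self.mu + self.k * self.sigma


@dataclass(frozen=True)
class PerturbedGeneSets:
    """Per-stage selected genes and the thresholded (final) score matrix.

    ``final[i, j]`` equals the grouped score where it lies strictly outside
    the band and 0 inside; gene i is in stage j's set iff final[i, j] != 0.
    """

    gene_ids: tuple[str, ...]
    stage_labels: tuple[str, ...]
    final: np.ndarray
    threshold: ThresholdSpec

    def genes_for(self, stage: str) -> frozenset[str]:
        j = self.stage_labels.index(stage)
        mask = self.final[:, j] != 0.0
        return frozenset(g for g, m in zip(self.gene_ids, mask) if m)

    def score_map(self, stage: str) -> dict[str, float]:
        j = self.stage_labels.index(stage)
        return {g: float(s) for g, s in zip(self.gene_ids, self.final[:, j])}

    @property
    def sets(self) -> dict[str, frozenset[str]]:
        return {s: self.genes_for(s) for s in self.stage_labels}


def perturbation_scores(matrix: ExpressionMatrix) -> PerturbationMatrix:
    """Score every gene at every time point as expression minus that gene's
    mean over all time points."""
    if matrix.n_timepoints < 2:
        raise ValueError(
            "perturbation scores need at least 2 time points; with one, "
            "mean-centered scores are identically zero"
        )
    scores = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    return PerturbationMatrix(matrix.gene_ids, matrix.time_labels, scores, grouped=False)


def group_scores(pm: PerturbationMatrix, grouping: TimeGrouping) -> PerturbationMatrix:
    """Average each gene's scores over the raw time points of each stage."""
    if pm.grouped:
        raise ValueError("scores are already grouped")
    grouping.validate_against(pm.stage_labels)
    col = {label: j for j, label in enumerate(pm.stage_labels)}
    stage_scores = np.column_stack(
        [pm.scores[:, [col[c] for c in cols]].mean(axis=1) for _, cols in grouping.stages]
    )
    return PerturbationMatrix(pm.gene_ids, grouping.stage_labels, stage_scores, grouped=True)


def compute_threshold(pm: PerturbationMatrix, k: float = 1.0) -> ThresholdSpec:
    """Mean +/- k * sample standard deviation of ALL score entries, pooled
    across genes and stages."""
    pooled = pm.scores.ravel()
    if pooled.size < 2:
        raise ValueError("need at least 2 scores to compute a threshold")
    mu = float(pooled.mean())
    sigma = float(pooled.std(ddof=1))
    if sigma == 0.0:
        raise ValueError(
            "all perturbation scores are equal (sigma = 0); "
            "supply a manual threshold instead"
        )
    return ThresholdSpec(mu=mu, sigma=sigma, k=k)


def select_perturbed(pm: PerturbationMatrix, spec: ThresholdSpec) -> PerturbedGeneSets:
    """Zero every score inside the closed band [lower, upper]; the survivors
    (strictly outside) define each stage's perturbed gene set."""
    outside = (pm.scores > spec.upper) | (pm.scores < spec.lower)
    final = np.where(outside, pm.scores, 0.0)
    return PerturbedGeneSets(pm.gene_ids, pm.stage_labels, final, spec)
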