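"""Resampling significance test for the observed score shift of the common
network.

Null model ("pooled", default): pool the union of all observed stage-network
edges, draw for every stage a uniform without-replacement sample of that
stage's observed edge count, intersect the draws, and compute the shift
statistic of the random common network between the tested stage pair; repeat
n_iter times.  An empty random intersection contributes 0 (the empty count is
reported).

An alternative null ("label-permute") keeps the observed common network fixed
and recomputes the statistic under a random permutation of the stage labels
of the score matrix.

Both an empirical p-value (add-one rank formula, never exactly 0) and a
one-sided normal-approximation p-value from the null sample mean/sd are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .network import CommonNetwork, StageNetwork, average_delta_p, common_network
from .perturbation import PerturbationMatrix

NULL_METHODS = ("pooled", "label-permute")


@dataclass(frozen=True)
class NullDistribution:
    n_iter: int
    values: np.ndarray
    n_empty: int
    seed: int | None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if values.shape != (self.n_iter,):
            raise ValueError("null distribution length must equal n_iter")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if self.n_iter > 1 else 0.0


@dataclass(frozen=True)
class TestResult:
    stage_a: str
    stage_b: str
    observed: float
    null: NullDistribution
    p_empirical: float
    p_parametric: float  # NaN when the null sd is 0
    null_method: str
    seed: int | None

    @property
    def n_iter(self) -> int:
        return self.null.n_iter


def pooled_edges(stage_networks: Sequence[StageNetwork]) -> tuple[tuple[str, str], ...]:
    """Union of all stage networks' edges, in sorted (deterministic) order."""
    if len(stage_networks) < 2:
        raise ValueError(f"need at least 2 stage networks, got {len(stage_networks)}")
    pool = frozenset.union(*(sn.edges for sn in stage_networks))
    if not pool:
        raise ValueError("pooled edge set is empty")
    return tuple(sorted(pool))


def sample_random_stage_networks(
    pool: Sequence[tuple[str, str]],
    sizes: Sequence[int],
    rng: np.random.Generator,
) -> list[StageNetwork]:
    """Per stage, a uniform without-replacement draw of the given edge count
    from the pool; draws are independent across stages."""
    pool = tuple(pool)
    nets = []
    for i, size in enumerate(sizes):
        if size > len(pool):
            raise ValueError(f"requested {size} edges from a pool of {len(pool)}")
        idx = rng.choice(len(pool), size=size, replace=False)
        nets.append(StageNetwork(f"random_{i}", frozenset(pool[j] for j in idx)))
    return nets


def empirical_p_value(null_values: np.ndarray, observed: float) -> float:
    """Add-one upper-tail rank: (1 + #{null >= observed}) / (N + 1)."""
    null_values = np.asarray(null_values, dtype=float)
    return float((1 + int((null_values >= observed).sum())) / (null_values.size + 1))


def parametric_p_value(observed: float, null_mean: float, null_sd: float) -> float:
    """One-sided upper tail of N(null_mean, null_sd) at the observed value;
    NaN when the null sd is 0."""
    if null_sd <= 0:
        return float("nan")
    return float(stats.norm.sf(observed, loc=null_mean, scale=null_sd))


def _delta_p_arrays(
    pool: Sequence[tuple[str, str]],
    pm: PerturbationMatrix,
    stage_a: str,
    stage_b: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pool-edge endpoint gene indices (-1 if absent from pm) and the
    per-gene |score(a) - score(b)| vector."""
    index = pm.gene_index()
    u_idx = np.array([index.get(u, -1) for u, _ in pool], dtype=np.int64)
    v_idx = np.array([index.get(v, -1) for _, v in pool], dtype=np.int64)
    ja, jb = pm.stage_index(stage_a), pm.stage_index(stage_b)
    gene_diff = np.abs(pm.scores[:, ja] - pm.scores[:, jb])
    return u_idx, v_idx, gene_diff


def significance_test(
    stage_networks: Sequence[StageNetwork],
    pm: PerturbationMatrix,
    stage_pair: tuple[str, str],
    n_iter: int = 10_000,
    seed: int | None = None,
    null_method: str = "pooled",
    rng: np.random.Generator | None = None,
) -> TestResult:
    """Resampling test of whether the observed shift statistic exceeds what
    same-sized random stage networks produce."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if null_method not in NULL_METHODS:
        raise ValueError(f"unknown null method {null_method!r}; expected one of {NULL_METHODS}")
    stage_a, stage_b = stage_pair
    if rng is None:
        rng = np.random.default_rng(seed)

    observed_common = common_network(stage_networks)
    if not observed_common.edges:
        raise ValueError("observed common network is empty; nothing to test")
    observed = average_delta_p(observed_common, pm, stage_a, stage_b).delta_p

    if null_method == "pooled":
        null_values, n_empty = _pooled_null(
            stage_networks, pm, stage_a, stage_b, n_iter, rng
        )
    else:
        null_values = _label_permute_null(
            observed_common, pm, stage_a, stage_b, n_iter, rng
        )
        n_empty = 0

    null = NullDistribution(n_iter=n_iter, values=null_values, n_empty=n_empty, seed=seed)
    return TestResult(
        stage_a=stage_a,
        stage_b=stage_b,
        observed=observed,
        null=null,
        p_empirical=empirical_p_value(null_values, observed),
        p_parametric=parametric_p_value(observed, null.mean, null.sd),
        null_method=null_method,
        seed=seed,
    )


def _pooled_null(
    stage_networks: Sequence[StageNetwork],
    pm: PerturbationMatrix,
    stage_a: str,
    stage_b: str,
    n_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    pool = pooled_edges(stage_networks)
    sizes = [len(sn) for sn in stage_networks]
    n_stages = len(stage_networks)
    u_idx, v_idx, gene_diff = _delta_p_arrays(pool, pm, stage_a, stage_b)

    values = np.zeros(n_iter, dtype=float)
    n_empty = 0
    counts = np.empty(len(pool), dtype=np.int32)
    for it in range(n_iter):
        counts[:] = 0
        for size in sizes:
            counts[rng.choice(len(pool), size=size, replace=False)] += 1
        common = np.flatnonzero(counts == n_stages)
        if common.size == 0:
            n_empty += 1
            continue  # records 0
        members = np.unique(np.concatenate((u_idx[common], v_idx[common])))
        members = members[members >= 0]
        if members.size == 0:
            n_empty += 1
            continue
        values[it] = gene_diff[members].mean()
    return values, n_empty


def _label_permute_null(
    observed_common: CommonNetwork,
    pm: PerturbationMatrix,
    stage_a: str,
    stage_b: str,
    n_iter: int,
    rng: np.random.Generator,
) -> np.ndarray:
    # Permuting stage labels of the observed networks leaves their edge-set
    # intersection unchanged, so the permutation acts on the score columns:
    # the statistic is recomputed between the permuted images of the pair,
    # over the fixed observed common network.
    index = pm.gene_index()
    members = np.array(
        [index[g] for g in sorted(observed_common.nodes) if g in index], dtype=np.int64
    )
    scores = pm.scores[members, :]
    ja, jb = pm.stage_index(stage_a), pm.stage_index(stage_b)
    n_stages = scores.shape[1]
    values = np.empty(n_iter, dtype=float)
    for it in range(n_iter):
        perm = rng.permutation(n_stages)
        values[it] = np.abs(scores[:, perm[ja]] - scores[:, perm[jb]]).mean()
    return values
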