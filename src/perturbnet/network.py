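"""Stage-specific network construction, common-network extraction, and the
average score-shift statistic between two stages.

A stage network keeps every scaffold edge with at least one endpoint in that
stage's perturbed gene set.  The common network is the exact set intersection
of all stage networks' edges.  The shift statistic between two stages is the
mean absolute difference of grouped (pre-threshold) scores over the common
network's member genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import InteractionSet
from .perturbation import PerturbationMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StageNetwork:
    stage_label: str
    edges: frozenset[tuple[str, str]]

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(g for e in self.edges for g in e)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class CommonNetwork:
    edges: frozenset[tuple[str, str]]

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(g for e in self.edges for g in e)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class DeltaPResult:
    """Mean absolute grouped-score difference over common-network members."""

    stage_a: str
    stage_b: str
    delta_p: float
    n_members: int
    n_skipped: int = 0


def build_stage_network(
    perturbed: Iterable[str], scaffold: InteractionSet, stage_label: str
) -> StageNetwork:
    """Keep scaffold edges with >= 1 endpoint in the perturbed set."""
    perturbed = frozenset(perturbed)
    if not perturbed:
        logger.warning("stage %r has an empty perturbed gene set", stage_label)
    edges = frozenset(
        (u, v) for u, v in scaffold.edges if u in perturbed or v in perturbed
    )
    return StageNetwork(stage_label, edges)


def common_network(stage_networks: Sequence[StageNetwork]) -> CommonNetwork:
    """Exact intersection of all stage networks' edge sets."""
    if len(stage_networks) < 2:
        raise ValueError(f"need at least 2 stage networks, got {len(stage_networks)}")
    edges = frozenset.intersection(*(sn.edges for sn in stage_networks))
    if not edges:
        logger.warning("common network is empty")
    return CommonNetwork(edges)


def average_delta_p(
    common: CommonNetwork,
    pm: PerturbationMatrix,
    stage_a: str,
    stage_b: str,
) -> DeltaPResult:
    """Average |score(stage_a) - score(stage_b)| over the common network's
    member genes, using grouped pre-threshold scores.

    Members are ALL nodes of the common network, including passive endpoints
    that were never individually selected.  Member genes absent from ``pm``
    are skipped and counted in ``n_skipped``.
    """
    if not common.edges:
        raise ValueError("delta-P is undefined on an empty common network")
    ja = pm.stage_index(stage_a)
    jb = pm.stage_index(stage_b)
    index = pm.gene_index()
    members = sorted(common.nodes)
    diffs = [
        abs(float(pm.scores[index[g], ja]) - float(pm.scores[index[g], jb]))
        for g in members
        if g in index
    ]
    n_skipped = len(members) - len(diffs)
    if not diffs:
        raise ValueError("no common-network member gene has perturbation scores")
    if n_skipped:
        logger.info("delta-P: skipped %d member gene(s) absent from the score matrix", n_skipped)
    return DeltaPResult(
        stage_a=stage_a,
        stage_b=stage_b,
        delta_p=sum(diffs) / len(diffs),
        n_members=len(diffs),
        n_skipped=n_skipped,
    )


def restrict_to_gene_list(
    scaffold: InteractionSet,
    pm: PerturbationMatrix,
    genes: Iterable[str],
) -> tuple[InteractionSet, PerturbationMatrix]:
    """Reduce the scaffold to edges with BOTH endpoints in ``genes`` and the
    score matrix to the listed genes (original order preserved)."""
    genes = frozenset(genes)
    if not genes:
        raise ValueError("gene list is empty")
    keep = [i for i, g in enumerate(pm.gene_ids) if g in genes]
    if not keep:
        raise ValueError("no listed gene is present in the score matrix")
    sub_pm = PerturbationMatrix(
        tuple(pm.gene_ids[i] for i in keep),
        pm.stage_labels,
        pm.scores[keep, :],
        grouped=pm.grouped,
    )
    edges = frozenset((u, v) for u, v in scaffold.edges if u in genes and v in genes)
    if not edges:
        logger.warning("gene-list restriction left an empty scaffold")
    return InteractionSet(edges), sub_pm
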