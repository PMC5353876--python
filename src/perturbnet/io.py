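"""Readers and writers for expression tables, interaction lists, gene lists,
grouping configs, networks, score tables, and key/value reports.

Gene identifiers are opaque, case-sensitive strings; no symbol normalization
is performed.  Edges are canonicalized lexicographically so that identical
edge sets always serialize identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

logger = logging.getLogger(__name__)

EXPRESSION_DIALECTS = ("plain_tsv", "series_matrix")
NETWORK_FORMATS = ("graphml", "edge_tsv")


class FormatError(ValueError):
    """A file does not conform to its expected format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class ExpressionMatrix:
    """Gene x time-point real-valued expression table.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` at
    ``time_labels[j]``, in whatever units the input provides (no transform is
    applied).  Gene identifiers must be unique unless ``allow_duplicate_genes``
    is set (the escape hatch used before duplicate collapsing).
    """

    gene_ids: tuple[str, ...]
    time_labels: tuple[str, ...]
    values: np.ndarray
    allow_duplicate_genes: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "time_labels", tuple(self.time_labels))
        if len(self.gene_ids) < 1:
            raise FormatError("expression matrix must contain at least one gene")
        if len(self.time_labels) < 2:
            raise FormatError(
                "expression matrix must contain at least two time points, "
                f"got {len(self.time_labels)}"
            )
        if values.shape != (len(self.gene_ids), len(self.time_labels)):
            raise FormatError(
                f"values shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.time_labels)} time points"
            )
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite expression value for gene {self.gene_ids[i]!r} "
                f"at column {self.time_labels[j]!r}"
            )
        if len(set(self.time_labels)) != len(self.time_labels):
            raise FormatError("time-point labels must be unique")
        if not self.allow_duplicate_genes:
            seen: set[str] = set()
            for g in self.gene_ids:
                if g in seen:
                    raise FormatError(
                        f"duplicate gene id {g!r}; collapse duplicates first "
                        "or read with allow_duplicate_genes=True"
                    )
                seen.add(g)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_timepoints(self) -> int:
        return len(self.time_labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.time_labels == other.time_labels
            and np.array_equal(self.values, other.values)
        )

    __hash__ = None  # type: ignore[assignment]


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Order an endpoint pair lexicographically."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class InteractionSet:
    """Undirected, deduplicated gene-gene edge set (the PPI scaffold).

    Edges are stored as lexicographically ordered pairs; self-loops are
    forbidden.
    """

    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", frozenset(self.edges))
        for u, v in self.edges:
            if u == v:
                raise FormatError(f"self-loop on {u!r} is not allowed")
            if u > v:
                raise FormatError(
                    f"edge ({u!r}, {v!r}) is not canonical; use from_pairs()"
                )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "InteractionSet":
        """Build a set from arbitrary pairs, dropping self-loops and merging
        duplicates under endpoint reordering."""
        edges = {canonical_edge(u, v) for u, v in pairs if u != v}
        return cls(frozenset(edges))

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(g for e in self.edges for g in e)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_edge(*pair) in self.edges


@dataclass(frozen=True)
class TimeGrouping:
    """Ordered mapping of stage labels to disjoint lists of raw time labels."""

    stages: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        stages = tuple((label, tuple(cols)) for label, cols in self.stages)
        object.__setattr__(self, "stages", stages)
        if len(stages) < 2:
            raise FormatError(f"grouping needs at least two stages, got {len(stages)}")
        labels = [label for label, _ in stages]
        if len(set(labels)) != len(labels):
            raise FormatError("stage labels must be unique")
        seen: set[str] = set()
        for label, cols in stages:
            if not cols:
                raise FormatError(f"stage {label!r} has no time points")
            for c in cols:
                if c in seen:
                    raise FormatError(f"time point {c!r} assigned to more than one stage")
                seen.add(c)

    @property
    def stage_labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.stages)

    @property
    def all_time_labels(self) -> tuple[str, ...]:
        return tuple(c for _, cols in self.stages for c in cols)

    def validate_against(self, time_labels: Sequence[str]) -> None:
        known = set(time_labels)
        for label, cols in self.stages:
            for c in cols:
                if c not in known:
                    raise FormatError(
                        f"stage {label!r} references unknown time point {c!r}"
                    )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _split_fields(line: str) -> list[str]:
    if "\t" in line:
        return [f.strip().strip('"') for f in line.rstrip("\n").split("\t")]
    return [f.strip('"') for f in line.split()]


def read_expression_table(
    path: str | Path,
    dialect: str = "plain_tsv",
    allow_duplicate_genes: bool = False,
) -> ExpressionMatrix:
    """Parse a TSV expression table: first column gene id, header row of
    time labels.

    ``dialect="series_matrix"`` additionally skips "!"-prefixed metadata lines
    and, when present, restricts parsing to the table between the
    ``!series_matrix_table_begin``/``end`` markers.  Plain TSV treats lines
    starting with "#" as comments.
    """
    if dialect not in EXPRESSION_DIALECTS:
        raise FormatError(
            f"unknown expression dialect {dialect!r}; expected one of {EXPRESSION_DIALECTS}"
        )
    path = Path(path)
    raw = path.read_text().splitlines()

    if dialect == "series_matrix":
        begin = [i for i, ln in enumerate(raw) if ln.startswith("!series_matrix_table_begin")]
        end = [i for i, ln in enumerate(raw) if ln.startswith("!series_matrix_table_end")]
        if begin and end:
            raw = raw[begin[0] + 1 : end[0]]
        comment = "!"
    else:
        comment = "#"
    lines = [ln for ln in raw if ln.strip() and not ln.startswith(comment)]
    if not lines:
        raise FormatError(f"{path}: no table content found")

    header = _split_fields(lines[0])
    time_labels = tuple(header[1:])
    if len(time_labels) < 2:
        raise FormatError(
            f"{path}: expression table needs at least 2 data columns, got {len(time_labels)}"
        )

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1:]:
        fields = _split_fields(ln)
        gene = fields[0]
        if len(fields) - 1 != len(time_labels):
            raise FormatError(
                f"{path}: gene {gene!r} has {len(fields) - 1} values, "
                f"expected {len(time_labels)}"
            )
        row: list[float] = []
        for label, cell in zip(time_labels, fields[1:]):
            try:
                row.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {cell!r} for gene {gene!r} "
                    f"at column {label!r}"
                ) from None
        gene_ids.append(gene)
        rows.append(row)
    if not gene_ids:
        raise FormatError(f"{path}: no gene rows found")
    return ExpressionMatrix(
        tuple(gene_ids),
        time_labels,
        np.array(rows, dtype=float),
        allow_duplicate_genes=allow_duplicate_genes,
    )


def read_interactions(path: str | Path) -> InteractionSet:
    """Parse a >=2-column TSV of gene symbols into a canonical edge set.

    Self-loops are dropped and duplicates (under endpoint reordering) merged;
    both counts are logged.  Lines starting with "#" are comments; fields
    beyond the first two are ignored.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    n_self = 0
    n_dup = 0
    n_lines = 0
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = _split_fields(ln)
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}")
        n_lines += 1
        u, v = fields[0], fields[1]
        if u == v:
            n_self += 1
            continue
        edge = canonical_edge(u, v)
        if edge in edges:
            n_dup += 1
        else:
            edges.add(edge)
    if n_lines == 0:
        raise FormatError(f"{path}: no interactions found")
    if n_self or n_dup:
        logger.info(
            "read_interactions(%s): dropped %d self-loop(s), merged %d duplicate(s)",
            path, n_self, n_dup,
        )
    logger.info("read_interactions(%s): %d edges", path, len(edges))
    return InteractionSet(frozenset(edges))


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Read one gene id per line; '#' lines are comments."""
    genes = frozenset(
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    )
    if not genes:
        raise FormatError(f"{path}: empty gene list")
    return genes


def read_grouping(path: str | Path) -> TimeGrouping:
    """Read a YAML/JSON mapping of stage label -> list of column labels.

    Mapping order defines stage order.
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, Mapping):
        raise FormatError(f"{path}: grouping file must be a mapping of stage -> columns")
    stages = []
    for label, cols in data.items():
        if isinstance(cols, str):
            cols = [cols]
        if not isinstance(cols, Sequence):
            raise FormatError(f"{path}: stage {label!r} must map to a list of columns")
        stages.append((str(label), tuple(str(c) for c in cols)))
    return TimeGrouping(tuple(stages))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as plain TSV (round-trips through
    :func:`read_expression_table`)."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(matrix.time_labels) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gene + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def write_network(
    network,
    path: str | Path,
    format: str = "edge_tsv",
    node_attrs: Mapping[str, Mapping[str, float]] | None = None,
) -> None:
    """Write an edge set as a 2-column TSV or GraphML.

    ``network`` is anything with an ``edges`` attribute containing canonical
    pairs (InteractionSet, StageNetwork, CommonNetwork).  ``node_attrs`` maps
    attribute name -> {gene: value} and is only carried by GraphML.
    """
    edges = sorted(network.edges)
    if format == "edge_tsv":
        with open(path, "w") as fh:
            for u, v in edges:
                fh.write(f"{u}\t{v}\n")
    elif format == "graphml":
        g = nx.Graph()
        g.add_edges_from(edges)
        if node_attrs:
            for name, mapping in node_attrs.items():
                nx.set_node_attributes(
                    g, {n: float(v) for n, v in mapping.items() if n in g}, name
                )
        nx.write_graphml(g, path)
    else:
        raise FormatError(f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}")


def read_network(path: str | Path, format: str = "edge_tsv") -> InteractionSet:
    """Read a network written by :func:`write_network` back as an edge set."""
    if format == "edge_tsv":
        return read_interactions(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        return InteractionSet.from_pairs((str(u), str(v)) for u, v in g.edges())
    raise FormatError(f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}")


def write_scores(gene_ids, stage_labels, scores, path: str | Path) -> None:
    """Write a gene x stage score table as TSV."""
    scores = np.asarray(scores, dtype=float)
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(stage_labels) + "\n")
        for gene, row in zip(gene_ids, scores):
            fh.write(gene + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def write_grouping(grouping: TimeGrouping, path: str | Path) -> None:
    data = {label: list(cols) for label, cols in grouping.stages}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def write_report(results: Mapping[str, object], path: str | Path) -> None:
    """Write a structured key/value text report (one ``key<TAB>value`` line
    per entry; nested mappings are flattened with dotted keys)."""

    def _flatten(prefix: str, obj: object, out: list[tuple[str, str]]) -> None:
        if isinstance(obj, Mapping):
            for k, v in obj.items():
                _flatten(f"{prefix}.{k}" if prefix else str(k), v, out)
        elif isinstance(obj, (list, tuple, set, frozenset)):
            out.append((prefix, json.dumps(sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj))))
        else:
            out.append((prefix, repr(obj) if isinstance(obj, float) else str(obj)))

    flat: list[tuple[str, str]] = []
    _flatten("", results, flat)
    with open(path, "w") as fh:
        for k, v in flat:
            fh.write(f"{k}\t{v}\n")


def read_report(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        k, _, v = ln.partition("\t")
        out[k] = v
    return out
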