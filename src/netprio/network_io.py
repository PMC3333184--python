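"""Readers, writers and the shared data model for gene networks.

The toolkit operates on three plain-text inputs:

* a gene network as a tab/whitespace-separated edge list
  (``gene_a  gene_b  [weight]``),
* a disease-association table (``family_id  gene_id``), and
* an optional gene-position table (``gene_id  chromosome  start``)
  used to build simulated-linkage candidate windows.

Gene identifiers are opaque strings; any identifier mapping (e.g. to
Entrez IDs) is the caller's responsibility.  Lines starting with ``#``
are comments.  In the edge-list format a single-column line declares an
isolated node, so that networks containing unconnected genes survive a
write/read round trip with an identical node set.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator, Mapping
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "NetworkFormatError",
    "LoadReport",
    "FamilyFilterReport",
    "GeneNetwork",
    "DiseaseFamilyTable",
    "GenePositionTable",
    "load_edge_list",
    "write_edge_list",
    "load_disease_families",
    "write_disease_families",
    "load_positions",
    "write_positions",
]


class NetworkFormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclasses.dataclass(frozen=True)
class LoadReport:
    """Bookkeeping emitted by :func:`load_edge_list`."""

    n_nodes: int
    n_edges: int
    self_loops_removed: int = 0
    duplicates_collapsed: int = 0
    zero_weight_dropped: int = 0


@dataclasses.dataclass(frozen=True)
class FamilyFilterReport:
    """Bookkeeping emitted by :func:`load_disease_families`."""

    n_families: int
    n_associations: int
    genes_dropped: int = 0
    families_dropped: int = 0


class GeneNetwork:
    """An undirected, weighted gene network.

    Wraps a :class:`networkx.Graph` whose edges carry a ``weight``
    attribute in (0, 1].  ``weighted`` distinguishes a functional
    association network (confidence-weighted edges) from a plain
    protein-interaction network, where every weight is forced to 1 and
    the strength of a gene reduces to its degree.

    Nodes are held in sorted order; all array/matrix views (adjacency
    matrix, strength vector) use that order, which makes every
    downstream computation deterministic.
    """

    def __init__(self, graph: nx.Graph, weighted: bool, report: LoadReport | None = None):
        for a, b, w in graph.edges(data="weight", default=None):
            if a == b:
                raise ValueError(f"self-loop on {a!r} is not allowed")
            if w is None or not (0.0 < w <= 1.0):
                raise ValueError(f"edge ({a!r}, {b!r}) has weight {w!r} outside (0, 1]")
            if not weighted and w != 1.0:
                raise ValueError("unweighted network must carry unit weights")
        self._graph = graph
        self.weighted = bool(weighted)
        self.nodes: tuple[str, ...] = tuple(sorted(graph.nodes))
        self.node_index: dict[str, int] = {g: i for i, g in enumerate(self.nodes)}
        self.report = report if report is not None else LoadReport(
            n_nodes=len(self.nodes), n_edges=graph.number_of_edges()
        )
        self._adjacency: sp.csr_matrix | None = None
        self._strengths: np.ndarray | None = None

    # -- basic container protocol -------------------------------------------------
    def __contains__(self, gene: str) -> bool:
        return gene in self._graph

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def graph(self) -> nx.Graph:
        """The underlying networkx graph (read-only by convention)."""
        return self._graph

    @property
    def number_of_nodes(self) -> int:
        return len(self.nodes)

    @property
    def number_of_edges(self) -> int:
        return self._graph.number_of_edges()

    def neighbors(self, gene: str) -> dict[str, float]:
        """Map neighbor -> edge weight for ``gene``."""
        if gene not in self._graph:
            raise KeyError(f"unknown gene {gene!r}")
        return {v: d["weight"] for v, d in self._graph.adj[gene].items()}

    def weight(self, i: str, j: str) -> float:
        """Edge weight between ``i`` and ``j`` (0 if no edge)."""
        d = self._graph.get_edge_data(i, j)
        return 0.0 if d is None else float(d["weight"])

    def degree(self, gene: str) -> int:
        if gene not in self._graph:
            raise KeyError(f"unknown gene {gene!r}")
        return int(self._graph.degree[gene])

    def strength(self, gene: str) -> float:
        """k_i: sum of weights of the gene's incident edges (= degree when unweighted)."""
        if gene not in self._graph:
            raise KeyError(f"unknown gene {gene!r}")
        return float(self.strengths[self.node_index[gene]])

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Edges as (a, b, weight) with a < b, in sorted order."""
        for a, b in sorted(tuple(sorted(e)) for e in self._graph.edges):
            yield a, b, self.weight(a, b)

    # -- array views ----------------------------------------------------------------
    @property
    def adjacency_matrix(self) -> sp.csr_matrix:
        """Symmetric weighted adjacency in node-sorted order (CSR, cached)."""
        if self._adjacency is None:
            self._adjacency = nx.to_scipy_sparse_array(
                self._graph, nodelist=self.nodes, weight="weight", format="csr"
            ).astype(float)
        return self._adjacency

    @property
    def strengths(self) -> np.ndarray:
        """Vector of k_i in node-sorted order (cached)."""
        if self._strengths is None:
            self._strengths = np.asarray(self.adjacency_matrix.sum(axis=1)).ravel()
        return self._strengths

    @property
    def total_strength(self) -> float:
        """Sum of k_g over all genes (twice the total edge weight)."""
        return float(self.strengths.sum())

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        weighted: bool,
        extra_nodes: Iterable[str] = (),
    ) -> "GeneNetwork":
        """Build a network from (a, b, weight) triples plus optional isolated nodes."""
        g = nx.Graph()
        g.add_nodes_from(extra_nodes)
        for a, b, w in edges:
            g.add_edge(a, b, weight=float(w))
        return cls(g, weighted=weighted)


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, whitespace-split fields), skipping blanks/comments."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def load_edge_list(
    path: str | Path, weighted: bool = False, weight_scale: float = 1.0
) -> GeneNetwork:
    """Load a gene network from a tab-separated edge list.

    Parameters
    ----------
    path
        Edge list with two gene columns and, in weighted mode, a third
        numeric weight column.  A single-column line declares an
        isolated node.
    weighted
        If False, every edge weight is forced to 1.
    weight_scale
        Divisor applied to raw weights: 1 for inputs already in [0, 1],
        1000 for STRING-style combined scores on a 0-1000 scale.

    Notes
    -----
    Self-loops are dropped, duplicate pairs (either orientation) are
    collapsed keeping the maximum weight, and edges whose rescaled
    weight is exactly 0 are dropped (indistinguishable from no edge).
    In weighted mode a header line is auto-detected when column 3 of
    the first data line does not parse as a number.
    """
    if weight_scale <= 0:
        raise ValueError("weight_scale must be positive")
    edges: dict[tuple[str, str], float] = {}
    isolated: set[str] = set()
    self_loops = duplicates = zero_dropped = 0
    first_data_line = True
    for lineno, fields in _data_lines(path):
        if len(fields) == 1:
            isolated.add(fields[0])
            first_data_line = False
            continue
        a, b = fields[0], fields[1]
        if weighted:
            if len(fields) < 3:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: weighted mode needs 3 columns, got {len(fields)}"
                )
            try:
                raw = float(fields[2])
            except ValueError:
                if first_data_line:  # header row
                    first_data_line = False
                    continue
                raise NetworkFormatError(
                    f"{path}: line {lineno}: weight {fields[2]!r} is not numeric"
                ) from None
            if not (0.0 <= raw <= weight_scale):
                raise NetworkFormatError(
                    f"{path}: line {lineno}: weight {raw} outside (0, {weight_scale}]"
                )
            w = raw / weight_scale
        else:
            w = 1.0
        first_data_line = False
        if a == b:
            self_loops += 1
            continue
        if w == 0.0:
            zero_dropped += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in edges:
            duplicates += 1
            edges[key] = max(edges[key], w)
        else:
            edges[key] = w
    if not edges:
        raise NetworkFormatError(f"{path}: empty network (no usable edges)")
    graph = nx.Graph()
    graph.add_nodes_from(isolated)
    for (a, b), w in edges.items():
        graph.add_edge(a, b, weight=w)
    report = LoadReport(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        self_loops_removed=self_loops,
        duplicates_collapsed=duplicates,
        zero_weight_dropped=zero_dropped,
    )
    return GeneNetwork(graph, weighted=weighted, report=report)


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    """Write a network back to edge-list form (round-trips exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        connected: set[str] = set()
        for a, b, w in network.edges():
            connected.update((a, b))
            if network.weighted:
                fh.write(f"{a}\t{b}\t{w:.17g}\n")
            else:
                fh.write(f"{a}\t{b}\n")
        for g in network.nodes:
            if g not in connected:
                fh.write(f"{g}\n")


class DiseaseFamilyTable(Mapping):
    """Mapping family_id -> frozenset of member gene identifiers.

    Families are the source of seed sets: in a leave-one-out trial one
    member is held out and the rest act as known disease genes.  Every
    family must have at least two members (a single-gene family cannot
    seed a trial for its own held-out gene).
    """

    def __init__(
        self,
        families: Mapping[str, Iterable[str]],
        report: FamilyFilterReport | None = None,
    ):
        self._families = {fid: frozenset(genes) for fid, genes in families.items()}
        for fid, members in self._families.items():
            if len(members) < 2:
                raise ValueError(f"family {fid!r} has fewer than 2 members")
        self.report = report if report is not None else FamilyFilterReport(
            n_families=len(self._families),
            n_associations=sum(len(m) for m in self._families.values()),
        )

    def __getitem__(self, fid: str) -> frozenset:
        return self._families[fid]

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._families))

    def __len__(self) -> int:
        return len(self._families)

    @property
    def total_associations(self) -> int:
        return sum(len(m) for m in self._families.values())


def load_disease_families(path: str | Path, network: GeneNetwork) -> DiseaseFamilyTable:
    """Load (family_id, gene_id) pairs and filter against the network.

    Member genes absent from the network are dropped first; families
    left with fewer than two members are then dropped entirely.
    """
    raw: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise NetworkFormatError(
                f"{path}: line {lineno}: expected 'family_id<TAB>gene_id'"
            )
        raw.setdefault(fields[0], set()).add(fields[1])
    genes_dropped = 0
    families_dropped = 0
    surviving: dict[str, set[str]] = {}
    for fid, members in raw.items():
        kept = {g for g in members if g in network}
        genes_dropped += len(members) - len(kept)
        if len(kept) >= 2:
            surviving[fid] = kept
        else:
            families_dropped += 1
    if not surviving:
        raise NetworkFormatError(f"{path}: no families survive filtering")
    report = FamilyFilterReport(
        n_families=len(surviving),
        n_associations=sum(len(m) for m in surviving.values()),
        genes_dropped=genes_dropped,
        families_dropped=families_dropped,
    )
    return DiseaseFamilyTable(surviving, report=report)


def write_disease_families(families: DiseaseFamilyTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for fid in families:
            for gene in sorted(families[fid]):
                fh.write(f"{fid}\t{gene}\n")


class GenePositionTable(Mapping):
    """Mapping gene_id -> (chromosome, start); defines per-chromosome gene order.

    Only the relative order along a chromosome is used (to pick flanking
    genes for the simulated-linkage scenario); ties on start coordinate
    are broken by gene identifier.
    """

    def __init__(self, positions: Mapping[str, tuple[str, int]]):
        self._positions = {g: (str(c), int(s)) for g, (c, s) in positions.items()}
        order: dict[str, list[str]] = {}
        for g, (c, s) in self._positions.items():
            order.setdefault(c, []).append(g)
        self._order = {
            c: tuple(sorted(gs, key=lambda g: (self._positions[g][1], g)))
            for c, gs in order.items()
        }

    def __getitem__(self, gene: str) -> tuple[str, int]:
        return self._positions[gene]

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._positions))

    def __len__(self) -> int:
        return len(self._positions)

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(sorted(self._order))

    def chromosome(self, gene: str) -> str:
        return self._positions[gene][0]

    def ordered_genes(self, chromosome: str) -> tuple[str, ...]:
        """Genes on a chromosome in (start, gene_id) order."""
        return self._order[chromosome]


def load_positions(path: str | Path) -> GenePositionTable:
    """Load a gene-position table (gene_id, chromosome, start)."""
    positions: dict[str, tuple[str, int]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise NetworkFormatError(
                f"{path}: line {lineno}: expected 'gene_id<TAB>chromosome<TAB>start'"
            )
        gene, chrom, start_s = fields[0], fields[1], fields[2]
        try:
            start = int(start_s)
        except ValueError:
            raise NetworkFormatError(
                f"{path}: line {lineno}: start {start_s!r} is not an integer"
            ) from None
        if start < 0:
            raise NetworkFormatError(f"{path}: line {lineno}: start must be >= 0")
        if gene in positions:
            raise NetworkFormatError(f"{path}: line {lineno}: duplicate gene {gene!r}")
        positions[gene] = (chrom, start)
    return GenePositionTable(positions)


def write_positions(positions: GenePositionTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in positions:
            chrom, start = positions[gene]
            fh.write(f"{gene}\t{chrom}\t{start}\n")
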