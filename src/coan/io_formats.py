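"""Domain containers and the plain-text formats the tool reads and writes.

Three containers travel through the whole pipeline:

* :class:`PPINetwork` — an undirected simple graph over opaque protein
  identifiers, with a deterministic vertex order (first appearance) so
  downstream matrices are reproducible.
* :class:`AnnotationMap` — protein -> set of GO-slim term identifiers.
* :class:`ComplexSet` — a list of protein sets (predicted or reference
  complexes).

File formats are deliberately minimal: two-column TSV edge lists (a SIF
"A rel B" variant behind a flag), two-column TSV or GAF 2.x annotation
tables, and one-complex-per-line TSV catalogues in the style of CYC2008.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from coan.errors import ParseError, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "AnnotationMap",
    "ComplexSet",
    "read_ppi_edgelist",
    "read_annotations",
    "read_complexes",
    "write_complexes",
    "write_ppi_edgelist",
    "write_annotations",
]


@dataclass(frozen=True)
class PPINetwork:
    """Undirected simple PPI graph G = (V, E).

    ``proteins`` keeps first-appearance order; ``edges`` holds unordered
    pairs as frozensets.  Self-loops and duplicate edges are rejected at
    construction — use :meth:`from_edges` for tolerant building.
    """

    proteins: tuple[str, ...]
    edges: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        pset = set(self.proteins)
        if len(pset) != len(self.proteins):
            raise ValueError("duplicate protein identifiers")
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")
            if not e <= pset:
                raise ValueError(f"edge endpoint outside protein set: {set(e)}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        proteins: Iterable[str] = (),
    ) -> "PPINetwork":
        """Build from an edge iterable; drops self-loops and duplicates.

        ``proteins`` may seed extra (possibly isolated) vertices; vertex
        order is first appearance across ``proteins`` then edge endpoints.
        """
        order: dict[str, None] = {}
        for p in proteins:
            order.setdefault(p, None)
        eset: set[frozenset[str]] = set()
        for u, v in edges:
            order.setdefault(u, None)
            order.setdefault(v, None)
            if u == v:
                continue
            eset.add(frozenset((u, v)))
        return cls(tuple(order), frozenset(eset))

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self.edges

    def neighbors(self, p: str) -> set[str]:
        return {next(iter(e - {p})) for e in self.edges if p in e}

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {p: set() for p in self.proteins}
        for e in self.edges:
            u, v = tuple(e)
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.proteins)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g


@dataclass(frozen=True)
class AnnotationMap:
    """Protein -> set of GO-slim identifiers; term order is deterministic."""

    terms: tuple[str, ...]
    by_protein: Mapping[str, frozenset[str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationMap":
        """Build from (protein, term) rows; repeated proteins union."""
        term_order: dict[str, None] = {}
        by_protein: dict[str, set[str]] = {}
        for protein, term in pairs:
            term_order.setdefault(term, None)
            by_protein.setdefault(protein, set()).add(term)
        return cls(tuple(term_order), {p: frozenset(ts) for p, ts in by_protein.items()})

    @classmethod
    def empty(cls) -> "AnnotationMap":
        return cls((), {})

    def terms_of(self, protein: str) -> frozenset[str]:
        return self.by_protein.get(protein, frozenset())

    def restricted_to(self, proteins: Iterable[str]) -> "AnnotationMap":
        """Keep only annotations of the given proteins; drop unused terms.

        Term order of the surviving terms is preserved.
        """
        keep = set(proteins)
        by_protein = {p: ts for p, ts in self.by_protein.items() if p in keep}
        dropped = len(self.by_protein) - len(by_protein)
        if dropped:
            logger.info("dropped annotations of %d proteins absent from the network", dropped)
        used = set().union(*by_protein.values()) if by_protein else set()
        return AnnotationMap(tuple(t for t in self.terms if t in used), by_protein)

    def __len__(self) -> int:
        return len(self.by_protein)


@dataclass
class ComplexSet:
    """An ordered collection of complexes (sets of protein identifiers)."""

    complexes: list[frozenset[str]] = field(default_factory=list)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        if any(not c for c in self.complexes):
            raise ValueError("empty complex")
        if self.labels is not None and len(self.labels) != len(self.complexes):
            raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def as_sets(self) -> list[frozenset[str]]:
        return list(self.complexes)

    def deduplicated(self) -> "ComplexSet":
        """Collapse identical member sets, keeping first occurrence order."""
        seen: dict[frozenset[str], None] = {}
        for c in self.complexes:
            seen.setdefault(c, None)
        return ComplexSet(list(seen))

    @property
    def largest_size(self) -> int:
        return max((len(c) for c in self.complexes), default=0)


# ---------------------------------------------------------------------------
# readers / writers


def _data_lines(path: str | Path, comment: str = "#"):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith(comment):
                continue
            yield lineno, line


def read_ppi_edgelist(path: str | Path, sif: bool = False) -> PPINetwork:
    """Read a PPI network from a whitespace/tab-separated edge list.

    First two fields are the endpoints; extra columns (confidence scores
    etc.) are ignored.  With ``sif=True`` the SIF three-column form
    ``A relation B`` is expected and the endpoints are fields 1 and 3.
    Self-loops and duplicate undirected edges are dropped (and counted in
    the log).  An empty file yields an empty network.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    dropped_loops = 0
    for lineno, line in _data_lines(path):
        fields = line.split()
        if sif:
            if len(fields) < 3:
                raise ParseError("SIF line needs 3 fields", str(path), lineno)
            u, v = fields[0], fields[2]
        else:
            if len(fields) < 2:
                raise ParseError("edge line needs at least 2 fields", str(path), lineno)
            u, v = fields[0], fields[1]
        if u == v:
            dropped_loops += 1
        edges.append((u, v))
    net = PPINetwork.from_edges(edges)
    n_dup = len(edges) - dropped_loops - net.n_edges
    if dropped_loops or n_dup:
        logger.info(
            "%s: dropped %d self-loops, collapsed %d duplicate edges",
            path.name, dropped_loops, n_dup,
        )
    return net


def write_ppi_edgelist(net: PPINetwork, path: str | Path) -> None:
    """Write the network as a 2-column TSV, one undirected edge per line.

    Only edges are written: isolated proteins do not survive a round-trip
    through :func:`read_ppi_edgelist` and callers that need them must keep
    the protein list separately.
    """
    index = {p: i for i, p in enumerate(net.proteins)}
    rows = sorted(
        (tuple(sorted(e, key=index.__getitem__)) for e in net.edges),
        key=lambda uv: (index[uv[0]], index[uv[1]]),
    )
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in rows:
            fh.write(f"{u}\t{v}\n")


_GAF_SYMBOL_COL = 2   # DB object symbol
_GAF_GOID_COL = 4
_GAF_ASPECT_COL = 8


def read_annotations(
    path: str | Path,
    format: str = "tsv",
    aspects: str | None = None,
) -> AnnotationMap:
    """Read protein -> GO-slim annotations.

    ``format='tsv'``: two columns, protein id then term id.
    ``format='gaf'``: GAF 2.x; uses the DB-object-symbol and GO-ID
    columns, skipping ``!`` comment lines.  ``aspects`` may restrict to a
    subset of {'P','F','C'} (default: keep all three aspects).
    """
    path = Path(path)
    if format not in ("tsv", "gaf"):
        raise UsageError(f"unknown annotation format: {format!r}")
    pairs: list[tuple[str, str]] = []
    if format == "tsv":
        for lineno, line in _data_lines(path):
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ParseError("annotation line needs 2 fields", str(path), lineno)
            pairs.append((fields[0], fields[1]))
    else:
        keep = set(aspects) if aspects else None
        for lineno, line in _data_lines(path, comment="!"):
            fields = line.split("\t")
            if len(fields) <= _GAF_GOID_COL:
                raise ParseError("GAF line too short", str(path), lineno)
            if keep is not None:
                if len(fields) <= _GAF_ASPECT_COL:
                    raise ParseError("GAF line lacks aspect column", str(path), lineno)
                if fields[_GAF_ASPECT_COL] not in keep:
                    continue
            pairs.append((fields[_GAF_SYMBOL_COL], fields[_GAF_GOID_COL]))
    return AnnotationMap.from_pairs(pairs)


def write_annotations(ann: AnnotationMap, path: str | Path) -> None:
    """Write a 2-column protein/term TSV (protein order, then term order)."""
    term_rank = {t: i for i, t in enumerate(ann.terms)}
    with open(path, "w", encoding="utf-8") as fh:
        for protein, terms in ann.by_protein.items():
            for t in sorted(terms, key=term_rank.__getitem__):
                fh.write(f"{protein}\t{t}\n")


def read_complexes(path: str | Path, labeled: bool = False) -> ComplexSet:
    """Read one complex per line, members tab-separated.

    With ``labeled=True`` the first field is a complex identifier.
    """
    path = Path(path)
    complexes: list[frozenset[str]] = []
    labels: list[str] = []
    for lineno, line in _data_lines(path):
        fields = [f for f in line.split("\t") if f]
        if labeled:
            if len(fields) < 2:
                raise ParseError("labeled complex line needs a label and >= 1 member", str(path), lineno)
            labels.append(fields[0])
            fields = fields[1:]
        if not fields:
            raise ParseError("complex line has no members", str(path), lineno)
        complexes.append(frozenset(fields))
    return ComplexSet(complexes, labels if labeled else None)


def write_complexes(cs: ComplexSet, path: str | Path) -> None:
    """Write one complex per line (members sorted); duplicates collapsed."""
    cs = cs.deduplicated()
    with open(path, "w", encoding="utf-8") as fh:
        for c in cs.complexes:
            fh.write("\t".join(sorted(c)) + "\n")
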