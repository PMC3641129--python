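"""Ontology augmented network and its random-walk transition matrix.

The augmented graph adds one "dummy" vertex per GO slim and connects it
to every network protein the slim annotates.  Two edge classes result:
PPI edges (protein-protein) and annotation edges (protein-term); there
are never term-term edges.

The transition matrix P over the combined vertex set is row-stochastic
with uniform steps over incident augmented edges:

* from protein v with PPI neighbours N(v) and annotation set A(v), each
  outgoing probability (to a neighbour protein or to an owned term) is
  1 / (|N(v)| + |A(v)|);
* from term a annotating proteins N(a), each entry is 1 / |N(a)|;
* term -> term entries are 0; vertices with no incident edge get an
  all-zero row (they can never seed or join a complex).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from coan.io_formats import AnnotationMap, PPINetwork

logger = logging.getLogger(__name__)

__all__ = ["AugmentedGraph", "TransitionMatrix", "build_augmented_graph", "transition_matrix"]

# dense representation below this vertex count, CSR above
SPARSE_THRESHOLD = 2000


@dataclass(frozen=True)
class AugmentedGraph:
    """PPI network plus GO dummy vertices.

    ``vertex_order`` is the network's protein order followed by the
    surviving term order; ``annotations`` is restricted to network
    proteins, with terms annotating zero network proteins dropped.
    """

    network: PPINetwork
    annotations: AnnotationMap

    @property
    def vertex_order(self) -> tuple[str, ...]:
        return self.network.proteins + self.annotations.terms

    @property
    def n_proteins(self) -> int:
        return self.network.n_proteins

    @property
    def n_terms(self) -> int:
        return len(self.annotations.terms)

    def annotation_edges(self) -> list[tuple[str, str]]:
        """All (protein, term) incidences in deterministic order."""
        term_rank = {t: i for i, t in enumerate(self.annotations.terms)}
        out = []
        for p in self.network.proteins:
            for t in sorted(self.annotations.terms_of(p), key=term_rank.__getitem__):
                out.append((p, t))
        return out


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix over proteins followed by terms."""

    matrix: np.ndarray | sp.csr_matrix
    vertex_order: tuple[str, ...]
    n_proteins: int
    n_terms: int

    @property
    def n(self) -> int:
        return self.n_proteins + self.n_terms

    def toarray(self) -> np.ndarray:
        if sp.issparse(self.matrix):
            return self.matrix.toarray()
        return self.matrix

    def dump_tsv(self, path: str | Path) -> None:
        """Write the labelled matrix as TSV (debug aid)."""
        dense = self.toarray()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t" + "\t".join(self.vertex_order) + "\n")
            for label, row in zip(self.vertex_order, dense):
                fh.write(label + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def build_augmented_graph(ppi: PPINetwork, ann: AnnotationMap) -> AugmentedGraph:
    """Attach GO dummy vertices to the PPI network.

    Annotations of proteins absent from the network are dropped (logged),
    as are terms left annotating no network protein.
    """
    return AugmentedGraph(ppi, ann.restricted_to(ppi.proteins))


def transition_matrix(ag: AugmentedGraph, sparse: bool | None = None) -> TransitionMatrix:
    """Build the row-stochastic transition matrix of the augmented graph.

    ``sparse=None`` picks dense below ``SPARSE_THRESHOLD`` vertices and
    CSR above; both representations agree to within 1e-10.
    """
    proteins = ag.network.proteins
    terms = ag.annotations.terms
    n_p, n_t = len(proteins), len(terms)
    n = n_p + n_t
    if sparse is None:
        sparse = n > SPARSE_THRESHOLD

    pidx = {p: i for i, p in enumerate(proteins)}
    tidx = {t: n_p + j for j, t in enumerate(terms)}

    adj = ag.network.adjacency()
    ann_of = {p: ag.annotations.terms_of(p) for p in proteins}
    term_proteins: dict[str, list[str]] = {t: [] for t in terms}
    for p in proteins:
        for t in ann_of[p]:
            term_proteins[t].append(p)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for p in proteins:
        deg = len(adj[p]) + len(ann_of[p])
        if deg == 0:
            continue
        w = 1.0 / deg
        i = pidx[p]
        for q in adj[p]:
            rows.append(i)
            cols.append(pidx[q])
            vals.append(w)
        for t in ann_of[p]:
            rows.append(i)
            cols.append(tidx[t])
            vals.append(w)
    for t in terms:
        members = term_proteins[t]
        if not members:
            continue
        w = 1.0 / len(members)
        i = tidx[t]
        for p in members:
            rows.append(i)
            cols.append(pidx[p])
            vals.append(w)

    mat = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    matrix: np.ndarray | sp.csr_matrix = mat if sparse else mat.toarray()
    return TransitionMatrix(matrix, ag.vertex_order, n_p, n_t)
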