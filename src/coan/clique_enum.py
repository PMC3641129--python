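"""Maximal clique enumeration on the original PPI network.

Candidate complexes start from the maximal cliques of size >= 3 of the
PPI graph (never the augmented graph — dummy vertices cannot be complex
members).  Enumeration delegates to networkx's pivoting Bron–Kerbosch
implementation; output order is canonicalised (sorted member tuples) so
downstream tie-breaking is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from coan.errors import UsageError
from coan.io_formats import PPINetwork

__all__ = ["Clique", "maximal_cliques"]


@dataclass(frozen=True)
class Clique:
    """A set of pairwise-interacting proteins."""

    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)

    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


def maximal_cliques(ppi: PPINetwork, min_size: int = 3) -> list[Clique]:
    """All maximal cliques of the PPI network with at least ``min_size`` members.

    Deterministic: results are sorted by (size descending, member tuple).
    """
    if min_size < 1:
        raise UsageError(f"min_size must be >= 1, got {min_size}")
    g = ppi.to_networkx()
    found = [frozenset(c) for c in nx.find_cliques(g) if len(c) >= min_size]
    found.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    return [Clique(c) for c in found]
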