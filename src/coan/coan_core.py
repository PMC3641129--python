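"""The COAN clustering algorithm: density-ranked seed cliques, expansion.

Two phases on top of the unified distance matrix R:

1.  **Seed selection.**  All maximal cliques (size >= ``min_clique``) are
    ranked by density — the mean symmetrised closeness over member pairs.
    Repeatedly the densest candidate becomes a seed; every remaining
    candidate that overlaps it loses the seed's members, survives only if
    at least ``min_clique`` members remain (density recomputed, ranking
    refreshed), and is otherwise removed.  Seeds are therefore pairwise
    disjoint.

2.  **Expansion.**  Each PPI neighbour p of a seed s is scored by the
    connectivity score — its mean closeness to the seed's members divided
    by the seed's density — and absorbed when the score reaches
    ``extend_thres``.  Expansion is a single pass against the fixed seed:
    accepted proteins do not recruit further candidates, which makes the
    accepted set shrink monotonically as the threshold rises.

Predicted complexes are the expanded seeds with exact duplicates
collapsed; a protein may appear in several complexes (expansions may
overlap even though seeds do not).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from coan.augmented_network import build_augmented_graph, transition_matrix
from coan.clique_enum import Clique, maximal_cliques
from coan.errors import UsageError
from coan.io_formats import AnnotationMap, ComplexSet, PPINetwork
from coan.unified_distance import DistanceMatrix, unified_distance

logger = logging.getLogger(__name__)

__all__ = [
    "CoanParams",
    "SeedSet",
    "clique_density",
    "select_seed_cliques",
    "connectivity_score",
    "expand_seed",
    "predict_complexes",
]


@dataclass(frozen=True)
class CoanParams:
    """Tunable parameters of the pipeline.

    c : geometric damping of the random walk, in (0, 1).
    extend_thres : minimum connectivity score for absorbing a neighbour.
    min_clique : smallest admissible clique (and pruned remainder) size.
    """

    c: float = 0.1
    extend_thres: float = 0.6
    min_clique: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.c < 1.0):
            raise UsageError(f"c must lie in (0, 1), got {self.c}")
        if self.extend_thres <= 0.0:
            raise UsageError(f"extend_thres must be > 0, got {self.extend_thres}")
        if self.min_clique < 3:
            raise UsageError(f"min_clique must be >= 3, got {self.min_clique}")


@dataclass
class SeedSet:
    """Disjoint seed cliques in selection order, with their densities."""

    seeds: list[Clique] = field(default_factory=list)
    densities: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seeds)

    def __iter__(self):
        return iter(self.seeds)


def clique_density(q: Clique | frozenset[str], R: DistanceMatrix) -> float:
    """Mean symmetrised closeness over the clique's unordered member pairs."""
    members = q.members if isinstance(q, Clique) else q
    if len(members) < 2:
        raise UsageError("density needs at least 2 members")
    pairs = list(itertools.combinations(sorted(members), 2))
    return sum(R.sym(u, v) for u, v in pairs) / len(pairs)


def _rank_key(density: float, members: frozenset[str]):
    # densest first; ties: larger clique, then lexicographic members
    return (-density, -len(members), tuple(sorted(members)))


def select_seed_cliques(
    cands: list[Clique],
    R: DistanceMatrix,
    min_clique: int = 3,
) -> SeedSet:
    """Greedy removal/pruning pass turning candidate cliques into disjoint seeds.

    The candidate list is re-ranked after every pruning round, since a
    pruned clique's density changes.
    """
    pool: list[tuple[float, frozenset[str]]] = [
        (clique_density(c, R), c.members) for c in cands
    ]
    out = SeedSet()
    while pool:
        pool.sort(key=lambda dc: _rank_key(*dc))
        density, seed = pool.pop(0)
        out.seeds.append(Clique(seed))
        out.densities.append(density)
        survivors: list[tuple[float, frozenset[str]]] = []
        for d, members in pool:
            if members & seed:
                remainder = members - seed
                if len(remainder) >= min_clique:
                    survivors.append((clique_density(remainder, R), remainder))
                # else: removed
            else:
                survivors.append((d, members))
        pool = survivors
    return out


def connectivity_score(p: str, s: Clique | frozenset[str], R: DistanceMatrix) -> float:
    """How strongly protein ``p`` attaches to seed ``s``.

    Mean closeness of p to the seed's members, normalised by the seed's
    own density so a score of 1 means "as close as the seed is internally".
    Returns 0 when the seed density is 0.
    """
    members = s.members if isinstance(s, Clique) else s
    if p in members:
        raise UsageError(f"protein {p!r} already belongs to the seed")
    denom = clique_density(members, R)
    if denom == 0.0:
        return 0.0
    mean_r = sum(R.sym(p, q) for q in members) / len(members)
    return mean_r / denom


def expand_seed(
    s: Clique | frozenset[str],
    ppi: PPINetwork,
    R: DistanceMatrix,
    extend_thres: float = 0.6,
) -> frozenset[str]:
    """Absorb every PPI neighbour whose connectivity score reaches the threshold.

    Single pass against the fixed seed: candidates are the neighbours of
    seed members only, and accepted proteins do not widen the candidate
    pool.
    """
    members = s.members if isinstance(s, Clique) else s
    adj = ppi.adjacency()
    candidates = sorted(
        {q for m in members if m in adj for q in adj[m]} - set(members)
    )
    accepted = [
        p for p in candidates if connectivity_score(p, members, R) >= extend_thres
    ]
    return frozenset(members | set(accepted))


def predict_complexes(
    ppi: PPINetwork,
    ann: AnnotationMap,
    params: CoanParams = CoanParams(),
) -> ComplexSet:
    """Full pipeline: augmented graph -> R -> cliques -> seeds -> expansion.

    Deterministic for fixed inputs and parameters.  Identical predicted
    complexes are collapsed (first occurrence kept).
    """
    cliques = maximal_cliques(ppi, params.min_clique)
    if not cliques:
        return ComplexSet([])
    ag = build_augmented_graph(ppi, ann)
    P = transition_matrix(ag)
    R = unified_distance(P, params.c)
    seeds = select_seed_cliques(cliques, R, params.min_clique)
    logger.info("selected %d disjoint seed cliques from %d candidates", len(seeds), len(cliques))
    complexes = [expand_seed(s, ppi, R, params.extend_thres) for s in seeds]
    return ComplexSet(complexes).deduplicated()
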