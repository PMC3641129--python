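"""Independent straight-line re-implementations used as test oracles.

Everything here is deliberately naive: exhaustive subset enumeration for
cliques, dictionary loops for the transition matrix, an explicitly
truncated walk series for the closeness matrix, and a literal transcription
of the two-phase seed/expand procedure with no shared data structures.
Nothing imports from the package's algorithmic modules.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_maximal_cliques(proteins, edges, min_size):
    """All maximal cliques of size >= min_size by exhaustive subset search."""
    eset = {frozenset(e) for e in edges}
    nodes = list(proteins)

    def is_clique(sub):
        return all(frozenset((u, v)) in eset for u, v in itertools.combinations(sub, 2))

    cliques = []
    for r in range(min_size, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if not is_clique(sub):
                continue
            extendable = any(
                all(frozenset((w, u)) in eset for u in sub)
                for w in nodes if w not in sub
            )
            if not extendable:
                cliques.append(frozenset(sub))
    return cliques


def naive_transition(proteins, terms, edges, by_protein):
    """Row-stochastic matrix over proteins + terms, built entry by entry."""
    eset = {frozenset(e) for e in edges}
    order = list(proteins) + list(terms)
    idx = {v: i for i, v in enumerate(order)}
    n = len(order)
    T = np.zeros((n, n))
    for p in proteins:
        nbrs = [q for q in proteins if q != p and frozenset((p, q)) in eset]
        owned = [t for t in terms if t in by_protein.get(p, set())]
        deg = len(nbrs) + len(owned)
        if deg == 0:
            continue
        for q in nbrs:
            T[idx[p], idx[q]] = 1.0 / deg
        for t in owned:
            T[idx[p], idx[t]] = 1.0 / deg
    for t in terms:
        annotated = [p for p in proteins if t in by_protein.get(p, set())]
        if not annotated:
            continue
        for p in annotated:
            T[idx[t], idx[p]] = 1.0 / len(annotated)
    return T, order


def naive_closeness(T, c, L):
    """Truncated damped walk series sum_{l=1..L} c(1-c)^l T^l."""
    n = T.shape[0]
    acc = np.zeros((n, n))
    power = np.eye(n)
    for l in range(1, L + 1):
        power = power @ T
        acc += c * (1.0 - c) ** l * power
    return acc


def naive_predict(proteins, edges, by_protein, c=0.1, extend_thres=0.6,
                  min_clique=3, L=400):
    """Literal two-phase pipeline: rank cliques, prune overlaps, expand seeds."""
    terms = []
    for p in proteins:
        for t in sorted(by_protein.get(p, set())):
            if t not in terms:
                terms.append(t)
    T, order = naive_transition(proteins, terms, edges, by_protein)
    R = naive_closeness(T, c, L)
    idx = {v: i for i, v in enumerate(order)}

    def r(u, v):
        return 0.5 * (R[idx[u], idx[v]] + R[idx[v], idx[u]])

    def density(members):
        pairs = list(itertools.combinations(sorted(members), 2))
        return sum(r(u, v) for u, v in pairs) / len(pairs)

    candidates = [frozenset(cq) for cq in naive_maximal_cliques(proteins, edges, min_clique)]
    seeds = []
    while candidates:
        candidates.sort(key=lambda m: (-density(m), -len(m), tuple(sorted(m))))
        top = candidates.pop(0)
        seeds.append(top)
        nxt = []
        for m in candidates:
            if m & top:
                rem = m - top
                if len(rem) >= min_clique:
                    nxt.append(rem)
            else:
                nxt.append(m)
        candidates = nxt

    eset = {frozenset(e) for e in edges}
    complexes = []
    for seed in seeds:
        dens = density(seed)
        neighbours = sorted({
            q for p in seed for q in proteins
            if q not in seed and frozenset((p, q)) in eset
        })
        grown = set(seed)
        for p in neighbours:
            score = 0.0 if dens == 0 else (sum(r(p, q) for q in seed) / len(seed)) / dens
            if score >= extend_thres:
                grown.add(p)
        complexes.append(frozenset(grown))

    seen = {}
    for cx in complexes:
        seen.setdefault(cx, None)
    return list(seen)
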