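"""Shared fixtures: toy instances and random-instance generators."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from coan.io_formats import AnnotationMap, PPINetwork


def complete_edges(nodes):
    return list(itertools.combinations(nodes, 2))


def random_instance(rng, n_min=4, n_max=12, p=0.4, n_terms_max=4, p_ann=0.3):
    """Random PPI network + random annotations (for property-style tests)."""
    n = int(rng.integers(n_min, n_max + 1))
    proteins = [f"v{i}" for i in range(n)]
    edges = [(u, v) for u, v in itertools.combinations(proteins, 2) if rng.random() < p]
    n_terms = int(rng.integers(0, n_terms_max + 1))
    pairs = [
        (p_, f"t{j}")
        for p_ in proteins
        for j in range(n_terms)
        if rng.random() < p_ann
    ]
    return (
        PPINetwork.from_edges(edges, proteins),
        AnnotationMap.from_pairs(pairs),
    )


def _toy(name, edges, ann_pairs, proteins=()):
    return (
        name,
        PPINetwork.from_edges(edges, proteins),
        AnnotationMap.from_pairs(ann_pairs),
    )


def toy_instances():
    """Small named instances (<= 10 proteins) exercising distinct shapes."""
    out = [
        _toy("triangle_shared_term",
             complete_edges("ABC"),
             [("A", "t1"), ("B", "t1"), ("C", "t1")]),
        _toy("two_cliques_bridge",
             complete_edges("ABCD") + complete_edges("EFGH") + [("D", "E")],
             [(p, "t1") for p in "ABCD"] + [(p, "t2") for p in "EFGH"]),
        _toy("overlapping_cliques",
             complete_edges("abcd") + complete_edges("cdef"),
             [(p, "t1") for p in "abcd"]),
        _toy("chain_no_triangle",
             [("A", "B"), ("B", "C"), ("C", "D")],
             [("A", "t1"), ("D", "t1")]),
        _toy("unannotated_triangle_pair",
             complete_edges("ABC") + complete_edges("CDE"),
             []),
    ]
    rng = np.random.default_rng(7)
    for k in range(3):
        net, ann = random_instance(rng, n_min=6, n_max=9, p=0.5)
        out.append((f"random_{k}", net, ann))
    return out


@pytest.fixture(scope="session")
def toys():
    return toy_instances()


@pytest.fixture(scope="session")
def default_benchmark():
    from coan.synthetic_benchmark import BenchmarkSpec, generate_benchmark

    return generate_benchmark(BenchmarkSpec())
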