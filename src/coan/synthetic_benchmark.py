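"""Planted-complex benchmark generator.

Emulates the situation the predictor assumes: dense, disjoint groups of
proteins (near-cliques) whose members share dedicated GO slims, embedded
in a sparse background with noise edges, missing intra-complex edges and
spurious annotations.  Defaults describe a small yeast-like toy: 10
planted complexes of 4–10 members in a 60-protein background, 90%
intra-complex wiring thinned by 10% false negatives, 2% background edge
probability, two dedicated slims per complex carried by 90% of members,
and a 5% chance per protein of each spurious slim.

All randomness flows from one ``numpy`` Generator seeded by ``spec.seed``
and is consumed in a fixed documented order (complex sizes -> memberships
-> intra edges -> deletions -> background edges -> annotations), so a
fixed seed reproduces the benchmark byte for byte.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from coan.errors import UsageError
from coan.io_formats import (
    AnnotationMap,
    ComplexSet,
    PPINetwork,
    write_annotations,
    write_complexes,
    write_ppi_edgelist,
)

__all__ = ["BenchmarkSpec", "generate_benchmark", "write_benchmark"]

# generated protein names are P0000..P9999
_NAMESPACE = 10_000


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of the planted-complex generator (all probabilities in [0,1])."""

    n_complexes: int = 10
    size_range: tuple[int, int] = (4, 10)
    p_in: float = 0.9
    p_fn: float = 0.1
    n_background: int = 60
    p_out: float = 0.02
    n_terms: int = 30
    terms_per_complex: int = 2
    p_share: float = 0.9
    p_noise_ann: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("p_in", "p_fn", "p_out", "p_share", "p_noise_ann"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise UsageError(f"{name} must lie in [0, 1], got {v}")
        if self.size_range[0] < 3 or self.size_range[0] > self.size_range[1]:
            raise UsageError(f"invalid size_range {self.size_range} (min >= 3 required)")
        if self.n_complexes < 0 or self.n_background < 0:
            raise UsageError("counts must be non-negative")
        if self.n_complexes * self.terms_per_complex > self.n_terms:
            raise UsageError(
                "n_terms too small for the dedicated slims: need at least "
                f"{self.n_complexes * self.terms_per_complex}, have {self.n_terms}"
            )
        if self.n_complexes * self.size_range[1] + self.n_background > _NAMESPACE:
            raise UsageError("requested protein count exceeds the P0000..P9999 namespace")


def generate_benchmark(spec: BenchmarkSpec) -> tuple[PPINetwork, AnnotationMap, ComplexSet]:
    """Draw one benchmark instance: (network, annotations, truth complexes)."""
    rng = np.random.default_rng(spec.seed)

    # 1. complex sizes, then disjoint memberships over fresh names
    lo, hi = spec.size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_complexes)
    counter = itertools.count()
    members: list[list[str]] = [
        [f"P{next(counter):04d}" for _ in range(s)] for s in sizes
    ]
    background = [f"P{next(counter):04d}" for _ in range(spec.n_background)]
    proteins = [p for grp in members for p in grp] + background

    # 2. intra-complex edges with p_in, 3. thinned by p_fn
    edges: set[frozenset[str]] = set()
    for grp in members:
        for u, v in itertools.combinations(grp, 2):
            if rng.random() < spec.p_in:
                edges.add(frozenset((u, v)))
    for grp in members:
        for u, v in itertools.combinations(grp, 2):
            e = frozenset((u, v))
            if e in edges and rng.random() < spec.p_fn:
                edges.discard(e)

    # 4. every other pair with p_out
    planted_pairs = {
        frozenset((u, v))
        for grp in members
        for u, v in itertools.combinations(grp, 2)
    }
    for u, v in itertools.combinations(proteins, 2):
        e = frozenset((u, v))
        if e in planted_pairs:
            continue
        if rng.random() < spec.p_out:
            edges.add(e)

    # 5. annotations: dedicated slims per complex, then spurious ones
    terms = [f"GO:{i:07d}" for i in range(spec.n_terms)]
    pairs: list[tuple[str, str]] = []
    k = spec.terms_per_complex
    for ci, grp in enumerate(members):
        dedicated = terms[ci * k : (ci + 1) * k]
        for p in grp:
            for t in dedicated:
                if rng.random() < spec.p_share:
                    pairs.append((p, t))
    noise_terms = terms[spec.n_complexes * k :]
    for p in proteins:
        for t in noise_terms:
            if rng.random() < spec.p_noise_ann:
                pairs.append((p, t))

    net = PPINetwork.from_edges(sorted(edges, key=lambda e: tuple(sorted(e))), proteins)
    ann = AnnotationMap.from_pairs(pairs)
    truth = ComplexSet([frozenset(grp) for grp in members])
    return net, ann, truth


def write_benchmark(spec: BenchmarkSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write ppi.tsv, ann.tsv, truth.tsv and spec.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, ann, truth = generate_benchmark(spec)
    paths = {
        "ppi": out / "ppi.tsv",
        "ann": out / "ann.tsv",
        "truth": out / "truth.tsv",
        "spec": out / "spec.json",
    }
    write_ppi_edgelist(net, paths["ppi"])
    write_annotations(ann, paths["ann"])
    write_complexes(truth, paths["truth"])
    meta = asdict(spec)
    meta["generator"] = "numpy.random.default_rng(PCG64)"
    paths["spec"].write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")
    return paths
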