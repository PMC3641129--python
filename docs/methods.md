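# Methods

## Model

`coan` treats complex prediction as seed-and-extend clustering on an
attributed graph.  The attribute side (GO-slim annotations) is folded
into the topology by adding one dummy vertex per slim, joined to every
protein it annotates.  A delay-damped random walk on this augmented
graph defines the unified closeness

    R = Σ_{l≥1} c(1−c)^l P^l = c(1−c) P (I − (1−c)P)^{-1},

where P steps uniformly over incident augmented edges (probability
1/(|N(v)|+|A(v)|) out of protein v; 1/|N(a)| out of term a; 0 between
terms).  Because the spectral radius of (1−c)P is ≤ 1−c < 1, the series
converges and the closed form is evaluated by solving the linear system
(I − (1−c)P)ᵀ X = Pᵀ rather than inverting.  Only the protein×protein
block of R is kept; entries are bounded by 1−c.  R is asymmetric for
unequal degrees, so every pairwise use takes the symmetrised
r(u,v) = (R[u,v]+R[v,u])/2 — density and connectivity treat closeness as
a property of an unordered pair.

Assumptions worth stating: PPI and annotation edges carry equal weight
(no ω_E/ω_A split is exposed); walks may pass through dummy vertices as
intermediate states — that is precisely the mechanism by which shared
slims add paths between co-annotated proteins; isolated vertices get
all-zero transition rows instead of self-loops, since a vertex with no
edges can never join a clique of size ≥ 3.

## Parameters

| name | default | meaning |
|---|---|---|
| `c` | 0.1 | geometric damping of the walk; smaller c weights long walks more. 0.1 is a conventional restart-strength setting for random-walk proximity on attributed graphs. |
| `extend_thres` | 0.6 | minimum connectivity score for absorbing a neighbour; because the score is normalised by seed density it is roughly unit-scaled, so a fixed threshold is meaningful across graphs. |
| `min_clique` | 3 | smallest admissible seed clique and pruned remainder. |
| `omega` (evaluation) | 0.2 | NA match threshold; comparison is ≥, so NA = 0.2 counts as a match. |

## Algorithmic choices

* **Density** is the *mean* pairwise symmetrised closeness, not the sum:
  means are size-independent, so cliques of different sizes compete on a
  common scale when ranked globally.
* **Seed selection** re-sorts the candidate pool after every pruning
  round (a pruned clique's density changes).  Ties in density break by
  larger size, then lexicographic member tuple — an arbitrary but fixed
  rule that makes runs reproducible.  A pruned remainder is still a
  clique (subset of a clique), so its density remains well defined.
* **Expansion is single-pass against the fixed seed**: candidates are
  the PPI neighbours of seed members, and accepted proteins do not
  recruit further candidates.  This yields strict monotonicity — the
  accepted set at a higher threshold is a subset of the set at a lower
  one — which iterative growth would not guarantee.
* Seeds are disjoint but expansions may overlap; identical predicted
  complexes are collapsed, keeping first occurrence.
* Maximal clique enumeration delegates to networkx's pivoting
  Bron–Kerbosch; output is canonicalised (size-descending, then member
  tuple) for reproducibility.  Cliques are enumerated on the PPI graph
  only — dummy vertices are never complex members.
* The transition matrix is assembled sparse and densified below 2000
  vertices; both paths agree to 1e-10.

## Evaluation conventions

Precision/recall/F1 count NA-matches in both directions (n_cp
predictions matched, n_cb references matched).  Sn/PPV/Acc use the
contingency table t_ij = |ref_i ∩ pred_j|: Sn = Σ_i max_j t_ij / Σ_i n_i,
PPV = Σ_j max_i t_ij / Σ_j Σ_i t_ij, Acc = √(Sn·PPV).  Predictions with
zero overlap against every reference are excluded from the PPV
denominator: a wholly-novel (possibly correct but unannotated) complex
should not dilute the overlap-concentration score.  Empty prediction or
reference sets report zeros with a logged warning.

## Synthetic benchmark

The generator plants `n_complexes` disjoint near-cliques (sizes uniform
in `size_range`) in a background of `n_background` proteins: planted
pairs are wired with probability `p_in` and then thinned by false-negative
rate `p_fn` (defaults 0.9 and 0.1, net 0.81 — dense but imperfect, as
high-throughput interactomes are); all other pairs appear with
`p_out` = 0.02.  Each complex owns `terms_per_complex` = 2 dedicated
slims, carried by each member with probability `p_share` = 0.9; every
protein also gains each slim of a 10-term noise vocabulary with
probability `p_noise_ann` = 0.05.  The slim vocabulary size is 30: 20
dedicated terms (10 complexes × 2) plus the noise pool.  One
`numpy.random.default_rng(seed)` stream is consumed in a fixed order
(sizes → memberships → intra edges → deletions → background edges →
annotations), so output is byte-reproducible; `spec.json` records the
generator name.

What it does *not* emulate: scale-free degree distributions, overlapping
complexes, shared housekeeping slims across complexes, or dataset-specific
identifier noise.  Passing the recovery tests therefore shows the
machinery is correct under the planted-structure assumptions, not that
comparable scores would be reached on a real interactome.

A note on the annotation mechanism: under equal edge weighting,
annotation edges divert walk mass onto term vertices, so *absolute*
protein-block closeness shrinks everywhere when annotations are added.
The discriminative effect is relative — on the default benchmark the
ratio of mean within-complex to mean between-complex closeness rises
(≈ 6.4 vs ≈ 5.6 without annotations), and for a pair of proteins whose
degrees are held fixed, replacing private slims by one shared slim
strictly increases their closeness.  The test suite pins both forms.

## Numerical choices and degenerate inputs

* c is validated to (0,1); the linear solve is guarded although the
  system cannot be singular under the spectral-radius bound.
* Zero-density seeds give connectivity score 0 (no neighbour is ever
  absorbed into them).
* Empty networks, annotation-free runs, empty complex files and
  header-only GAF files are all legal degenerate inputs yielding empty
  or annotation-free results, not errors.
* Protein identifiers are opaque, case-sensitive strings; no systematic
  name mapping is attempted.

## Test oracles and problem sizes

Each pipeline stage is checked against an independent route: the closed
form of R against an explicitly truncated 400-term series (truncation
tail (0.9)^401 ≈ 2·10⁻¹⁹ at c = 0.1, far below the 10⁻¹⁰ assertion
band); clique enumeration against exhaustive subset search on graphs of
up to 12 vertices; the full pipeline against a literal straight-line
transcription of the two-phase procedure on toy instances of ≤ 10
proteins.  Structural and recovery checks run on the default benchmark
(10 complexes, ≈ 130 proteins, 30 slims) and across ten generator seeds,
sizes at which the whole suite completes in a few seconds.

## Known limitations

* Equal PPI/annotation edge weighting is fixed; no per-annotation
  contribution weights.
* Binary networks only; confidence columns in edge lists are ignored.
* R is computed densely on the full vertex set (cubic solve), fine to a
  few thousand proteins; very large interactomes would need an
  iterative solver, which is out of scope.
* GO-enrichment p-values for predicted complexes are not computed.
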