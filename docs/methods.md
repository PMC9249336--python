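# Methods

## Problem setting

High-throughput protein–protein interaction (PPI) screens disagree: any
two large *E. coli* interaction datasets share only a small fraction of
their pairs. `ppitopo` treats this as two coupled problems. First, how
many cross-dataset overlaps would arise by chance alone, so that a
combined network can be restricted to statistically reliable
interactions? Second, what is the global shape of the resulting network
beyond degree-based descriptions — its cliques, cavities and cycles —
and how unusual is that shape relative to random controls?

## Random-overlap model (GHGD)

Let `m` datasets of sizes `n_1..n_m` be drawn independently and
uniformly from a universe of `N` potential interactions (for `P`
proteins, `N = P(P−1)/2`). For a fixed element, membership in dataset
`i` is Bernoulli with `p_i = n_i/N`, independent across datasets, so the
number of datasets containing it is Poisson-binomial. The count `X` of
elements in at least `k` datasets has

    E[X]   = N · P(B ≥ k)
    Var[X] = N·p(1−p) + N(N−1)·(p₂ − p²)

where `p = P(B ≥ k)` and `p₂` is the joint tail probability for two
fixed distinct elements, with per-dataset joint membership
probabilities `n_i(n_i−1)/(N(N−1))` (both) and `n_i(N−n_i)/(N(N−1))`
(exactly one), independent across datasets. Both are evaluated by exact
enumeration over membership patterns (`2^m` and `4^m` terms), so for a
handful of datasets the moments are effectively closed-form. Monte-Carlo
simulation of the actual without-replacement draws is the test oracle;
on small universes the exact moments sit within 3 standard errors of
10⁵-replicate simulations.

Because the distribution's shape is awkward, the confidence interval
uses Chebyshev's inequality, which needs only the two moments: with
probability ≥ 1−α the count lies within `sqrt(1/α)` standard deviations
of the mean (α defaults to 0.05, lower bound clipped at 0). The integer
`random_up = floor(upper bound)` is the worst-case number of chance
overlaps; `sig = observed − random_up` (floored at 0) of the observed
overlaps are then deemed statistically reliable, with a false-positive
share of `random_up / observed`.

For the study design of three datasets with sizes 11 017, 3 888 and
5 993 over `N = 3485·3484/2 = 6 070 870` potential pairs, the model
gives mean 21.76 and variance 21.66 for the ≥2-fold overlap count
(CI 0.94–42.57) and mean 0.007 for the 3-fold count (CI 0–0.38); against
1 142 observed ≥2-fold overlaps this bounds the false-positive share at
42/1142 ≈ 3.68%.

## Clique complex and GF(2) homology

The combined network's simplicial structure is its flag (clique)
complex: every `(q+1)`-clique is a `q`-simplex. Maximal cliques come
from networkx's pivoting Bron–Kerbosch enumeration; faces are expanded
from them. The biggest simplex dimension is reported as BDS. An optional
dimension cap guards against dense pathological inputs (faces below the
cap stay complete, so homology below the cap is exact).

Homology uses Z/2 coefficients throughout, which kills orientation
bookkeeping: a chain is a set of simplexes, addition is symmetric
difference, and the boundary of a `q`-simplex is the set of its
`(q−1)`-faces. Boundary matrices are stored column-wise as bit-packed
Python integers; ranks come from online-reduced GF(2) elimination
(exact, no floating point). Betti numbers follow the rank formula
`β_q = n_q − rank ∂_q − rank ∂_{q+1}`; the largest `q ≥ 1` with
`β_q > 0` is the biggest cavity dimension (BDC, 0 when no cavity
exists). Tests validate every complex against an independent dense
numpy elimination oracle, the Euler-characteristic identity, and
disjoint-union additivity.

### Minimal 1-cycle representatives

A 1-dimensional homology class is an equivalence class of cycles
modulo boundaries of filled triangles; the package reports one short
representative per class plus the homologous variants it encounters.
Candidates are each edge's shortest cycle (the edge plus the shortest
alternative path between its endpoints), sorted by length and reduced
greedily against the triangle-boundary basis, topped up by
spanning-forest fundamental cycles if the pool falls short; short
cycles therefore claim classes first, which avoids representatives
that accidentally wrap several cavities. Each representative is then
shortened further by exchanging an arc for a graph shortest path
whenever the exchange is verified homologous (the symmetric difference
reduces to zero against the triangle boundaries), iterated to a fixed
point with deterministic tie-breaks. This is a local heuristic: global
minimality is not guaranteed, a known limitation.

### Cycle involvement (q-DC) and cycle ranking

`q-DC` of a node is the number of `q`-dimensional homology classes
whose stored representatives pass through it. Since a full equivalence
class is exponentially large, membership is counted against a bounded
representative set: the minimal representative, every variant met while
shortening, plus `expand_depth` rounds (default 1) of single-triangle
perturbations that again form a simple cycle. Each class counts at most
once per node. Cycles are ranked by the mean `q-DC` over their member
nodes, descending, ties broken lexicographically. Only `q = 1` is
exposed; the networks of interest have at most one 2-cavity.

## Filtrations and persistence

A weighted network is filtered by adding edges in order of weight rank
(descending by default — a larger weight means a more reliable
interaction — with ties in the graph's edge iteration order, which is
deterministic), each edge dragging in every clique it completes, so
each filtration stage is the flag complex of the edges so far. Betti
curves recompute Betti numbers from scratch at every step; the sizes
involved make incremental updates unnecessary. Persistence intervals
come from the standard GF(2) column-reduction pairing; classes alive at
the end get an open death, and classes born and killed at the same
value are dropped by default. Explicitly listed filtrations (value →
simplexes) are supported for worked examples; a listed simplex whose
face was left implicit gets the face auto-inserted at the same step.

## Null models

* **RandomNet** — uniform G(n, m): exactly the source network's node and
  edge counts, sampled by choosing `m` distinct pairs uniformly
  (distribution-equivalent to adding one uniformly random new edge per
  step).
* **RandomNet-SameDD** — exact degree-sequence match. The realization is
  the randomized converse of the Havel–Hakimi reduction: saturate a node
  of minimal positive residual degree (random among ties) by connecting
  it to randomly ordered admissible partners, accepting an edge only if
  the residual sequence stays graphical under the Erdős–Gallai
  condition. Saturating the minimal-degree node first guarantees an
  admissible partner always exists (the same invariant behind the
  Blitzstein–Diaconis sequential algorithm); a naive random-node order
  dead-ends frequently on heavy-tailed sequences because the residual
  check cannot see already-placed edges. A restart cap remains as a
  safety net only.

Ensemble summaries report mean, sample SD (ddof = 1) and the
normal-approximation 95% CI `mean ± 1.96·SD` over seeded draws; the
default ensemble size is 100 and is configurable, and per-sample values
are retained for audit.

## Classical node metrics

Degree; local clustering `2e_i/(k_i(k_i−1))` with 0 below degree 2;
betweenness with fractional credit across co-minimal geodesics,
endpoints excluded, normalized by `(N−1)(N−2)/2` (the standard reading
of the normalization; an indicator-counting variant would differ);
harmonic closeness `(Σ 1/d)/(N−1)` so disconnected pairs contribute 0;
and per-node assortativity as the Pearson correlation between
reciprocal distance and a partner metric (degree, closeness or
betweenness), NaN when undefined. All are cross-checked against
brute-force geodesic enumeration on small fixtures.

## Synthetic data

The generators emulate the study's two input regimes and are exactly
reproducible from (parameters, seed):

* **Overlap scenarios** — datasets drawn from a shared pair universe
  with a planted true-interaction set retained per dataset with a
  detection probability, the rest uniform background. With nothing
  planted the overlap counts follow the GHGD null (calibration is a
  test); with full detection the planted pairs overlap everywhere.
  Defaults (300 proteins; dataset sizes 600/400/500; 80 true pairs;
  detection 0.8) mirror the real design's shape — three mid-sized
  datasets over a much larger pair universe with a reliable overlapping
  core — at desk scale.
* **Planted topology** — disjoint-then-bridged unions of chordless
  cycles of length ≥ 4 (one 1-cavity each), octahedra (the minimal flag
  complex homeomorphic to a hollow sphere; one 2-cavity each) and
  random trees (nothing), joined by bridge edges, which are cut edges
  and only merge components. Ground-truth Betti numbers follow by
  additivity.
* **Power-law degree sequences** — discrete `P(d) ∝ d^−γ` (default
  γ = 2.5, the scale-free range typical of PPI networks), parity-fixed
  and decremented to graphicality, so the degree-matched null always has
  a realizable target.

What the synthetic data does **not** emulate: biophysical interactome
structure (duplication–divergence growth, bait/prey asymmetries,
spoke/matrix artifacts of complex purification), correlated false
negatives between experimental methods, or identifier-mapping noise.
Passing tests show the statistics and topology machinery are correct on
networks with known ground truth, not that any particular biological
claim transfers.

## Problem sizes and numerical choices

Tests run the exact/oracle comparisons on graphs of ≤ 12 nodes (where
exhaustive enumeration is feasible), Monte-Carlo calibrations at
10⁴–10⁵ replicates on universes of ≤ 1000 elements, and null-model
properties over 100 seeds on 18–30-node sequences — sizes chosen so the
whole suite completes in well under a minute while keeping every
statistical check at ≥ 3-standard-error resolution. All randomness is
funneled through `numpy.random.default_rng` seeded per call; two runs
with the same configuration produce byte-identical outputs. GF(2)
arithmetic is exact integers; the only floating-point quantities are
probabilities, metric values and ensemble summaries.

## Known limitations

* Minimal cycle representatives are locally, not globally, minimal; the
  q-DC counts depend on the bounded representative set (configurable
  `expand_depth`), so nodes lying only on very distant homologous
  cycles may be under-credited.
* The overlap model treats datasets as uniform independent draws;
  real screens share systematic biases, so the chance-overlap bound is
  conservative in the direction of over-crediting reliability.
* Betti curves recompute homology per step; for networks far larger
  than the ~10³-edge scale this becomes the bottleneck.
* Reproducing the published *E. coli* table values (Betti (149, 79, 1),
  simplex censuses, per-protein 1-DC) requires the deposited edge
  lists, which the pipeline accepts as ordinary TSV input but does not
  bundle.
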