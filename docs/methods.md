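# Methods

This note documents the definitions, conventions and numerical choices
behind every descriptor in `netquant`, and the points where the design
was genuinely open.

## Scope and model

All descriptors operate on simple, undirected, unweighted, connected
graphs with vertex labels `1..n`. Disconnected graphs are rejected
rather than assigned infinite distances: every distance-based
descriptor in the catalogue assumes finite distances, and there is no
canonical disconnected convention that preserves their comparability.
Edge weights and directions are likewise rejected, not silently
dropped — the descriptors are defined on the unweighted topology, and
dropping attributes silently would let a weighted network masquerade
as its skeleton.

Distances are BFS hop counts; the `DistanceMatrix` carries the derived
quantities shared by many descriptors: distance degrees
`s_i = Σ_j d_ij`, diameter `ρ`, and the distance-frequency spectrum
`g_k` (unordered pairs at distance `k`). Every descriptor accepts an
optional precomputed distance matrix and computes one internally when
it is absent; the two paths are guaranteed (and tested) to agree, and
the batch runner computes each graph's matrix exactly once.

All logarithms are base 2 (entropies in bits), with `0·log 0 := 0`.

## Conventions where the literature is ambiguous

Several catalogue names admit more than one formula in the literature.
The conventions shipped here are:

- **Harary index**: `H = ½ Σ_{i≠j} d_ij^{-1}`. The reciprocal-square
  variant is available via the `exponent` parameter.
- **Compactness**: `C = 4W/(n(n−1))`, i.e. twice the mean inter-vertex
  distance; equals 2 exactly on complete graphs.
- **Product of row sums**: returned as `log2(Π s_i)` by default — the
  raw product exceeds double precision near n ≈ 30 — with a raw mode
  for small graphs.
- **Complexity index B**: `B = Σ_v deg(v)/s_v`, unnormalized.
- **Normalized edge complexity**: `E_N = 2m/n²`.
- **Bertz complexity**: the degree-based form
  `2m·log2(2m) − Σ_v deg(v)·log2 deg(v)`.
- **Bonchev–Trinajstić index 1**: the *total* equality form over the
  `K = n(n−1)/2` unordered pairs, `I_D = K·log2 K − Σ_k g_k·log2 g_k`
  (diagonal excluded). The mean form is a one-line change in
  `bonchev1` should it ever be needed.
- **Skorobogatov–Dobrynin set**: eccentricity per vertex, radius,
  diameter, average eccentricity, distance degrees, mean distance,
  unipolarity `min_v s_v`, centralization `2W − n·min_v s_v`,
  variation `max_v(s_v − min_u s_u)` and mean distance-degree
  deviation `(1/n)Σ_v |s_v − 2W/n|`. These names are frozen as the
  API; the original sources vary in naming.

None of the package's reproduced reference values depend on these
choices; they are documented so users comparing against other software
know exactly what is computed.

## Automorphism orbits

The topological information content is the Shannon entropy of the
orbit partition of the automorphism group — a symmetry measure, not a
branching measure (the path and the star on 7 vertices have different
Wiener indices but the path's orbit entropy exceeds the star's).
Orbits are computed exactly:

1. vertices are partitioned by cheap automorphism-invariant
   certificates (degree and the sorted distance-matrix row; orbits can
   only refine this partition);
2. within each class, vertices are merged by individualization: `u`
   and `v` share an orbit iff the two copies of the graph with `u`
   (respectively `v`) given a distinguishing color are isomorphic,
   decided by VF2++ with node labels.

This is exact for any graph; the pairwise isomorphism tests are
worst-case exponential but fast in practice, and an explicit bound
(`max_n`, default 2000) guards against accidental misuse. Equitable-
partition approximations were rejected because they can be strictly
coarser than true orbits, which would silently deflate the entropy.
The test-suite verifies the orbit partition against an exhaustive
permutation oracle on all free trees with up to 8 vertices and 100
random connected graphs, and against an independent automorphism-group
computation (python-igraph/BLISS) on the example trees.

## Balaban-like information indices

Both indices are J-type edge sums over a positive local invariant:
`m/(γ+1)·Σ_{(i,j)∈E} (x_i x_j)^{-1/2}` with γ the cyclomatic number.
Index U uses the local information on distance magnitudes
`u_i = s_i·log2 s_i − Σ_j d_ij·log2 d_ij`. On the two-vertex graph
every `u_i` is zero and the index is infinite; the package returns a
flagged `+inf` with a warning rather than raising, so batch runs over
network collections containing tiny graphs degrade gracefully.

The local invariant of index X is a known open point: the original
construction is not recoverable from sources available to this
package, and an extensive numerical search over candidate invariants
failed to reproduce published X values beyond ≈1e-3. The shipped
default uses `x_i = u_i` (X degenerates to U) and is clearly
documented as such; the published six-tree X row is retained as an
unverified reference constant (`BALABANLIKE2_TABLE_REFERENCE`) that no
test asserts.

## Parametric entropies

The information functional framework assigns each vertex a positive
value `f(v)` and the graph the entropy of `p_i = f(v_i)/Σ f`. The
j-sphere functional is `f(v) = Σ_{j=1}^{ρ} c_j·|S_j(v)|`: a *linear*
weighted sum of sphere cardinalities. An exponential-of-sum form was
considered and rejected because it is inconsistent with published
per-vertex functional values, which the linear form reproduces to six
decimals.

Coefficient pre-settings (`ρ` = diameter): constant `c_j = 1`, linear
`c_j = ρ−j+1`, quadratic `c_j = (ρ−j+1)²`, exponential
`c_j = ρ·e^{1−j}`. The exponential rule was decoded from published
per-vertex functional values: it solves all three distinct vertex
classes of the branched example tree simultaneously to six decimals
and reproduces the published entropies of four structurally
unambiguous example trees to four decimals. The linear and quadratic
rules are documented conventions (monotone non-increasing, as the
framework requires); no reproduced value depends on them. Custom
coefficient vectors must be strictly positive and non-increasing.

The reported `distance` is `λ·(log2 n − entropy)` with default
λ = 1000: the scaled gap to the maximum-entropy (uniform) distribution,
non-negative, zero exactly for vertex-transitive graphs. The entropy
itself is independent of λ and of uniform scaling of the coefficient
vector (both properties are tested to machine precision).

The path-length (`Σ c_j·j·|S_j|`), vertex-centrality
(`Σ c_j·|S_j|/j`) and degree–degree (`Σ c_j·Σ_{u∈S_j} deg u`)
functionals are documented reconstructions: plausible members of the
framework with the stated monotone structure, strictly positive on
connected graphs with at least one edge. No external reference value
pins them; they are exercised by property tests (positivity, entropy
bounds, isomorphism invariance, uniformity on vertex-transitive
graphs) only.

## Example fixtures

The six seven-vertex example trees (`figure2_graphs`, keyed `a`–`f`)
are reconstructions from published invariant values, not machine-read
drawings. Each tree matches at least two independent published
invariants (its Wiener index and its orbit entropy), and trees `a`,
`c`, `e`, `f` are additionally pinned by published parametric
entropies and, for `c`, the full per-vertex functional/probability
vectors. The labeling of `c` was chosen to match the published
per-vertex output ordering and is a reconstruction, not ground truth;
every descriptor is isomorphism-invariant, so the labeling affects
only the order of per-vertex output.

## Synthetic populations

`generate_population(n_graphs, n_vertices, branching_bias, seed)` grows
random trees vertex-by-vertex: each new vertex attaches to the hub
with probability `branching_bias`, otherwise extends the current path
end. Bias 0 yields paths (2 leaves), bias 1 stars (n−1 leaves), and
the expected leaf count — the operative notion of branching —
increases monotonically in between. This emulates only the branching
axis of real network populations: it produces trees (no cycles, so
cyclomatic-number-sensitive descriptors are constant), with a single
hub rather than hierarchical modularity, and no degree-distribution
heavy tails. Passing separation tests on these populations shows that
branching-sensitive descriptors order the two classes as designed; it
does not show that any descriptor separates real disease and control
networks, which requires inferred networks from real expression data
and is outside this package's scope.

The demonstration sizes used by the tests and the acceptance script —
populations of 50–100 trees on 20–30 vertices — were chosen as the
smallest sizes at which the permutation test on the mean Wiener
difference is conclusively significant (p < 0.05 with 999
permutations) while the full suite stays fast.

## Numerical notes

- Distance matrices are exact integers (BFS); no floating-point
  shortest paths.
- Entropies accumulate in double precision directly from the
  definition; the partition entropies involve at most n terms and need
  no compensated summation at descriptor scale.
- `product_of_row_sums` works in log space by default (see above).
- Ties in partitions (equal class sizes) need no tie-breaking: the
  entropy depends only on the size multiset.
- Random generators (`random_tree` via Prüfer sequences,
  `erdos_renyi` with bounded connectivity retries,
  `generate_population`) take explicit integer seeds and are
  bit-reproducible across runs; `erdos_renyi` raises after 1000
  unsuccessful connectivity retries rather than looping forever.

## Known limitations

- Exact orbits on graphs with thousands of vertices rely on VF2++
  individualization; pathological regular graphs can be slow even
  below the `max_n` bound.
- The Balaban-like X index is an alias of U pending a verifiable
  original formula (see above).
- Subgraph-isomorphism-based descriptors and the Hosoya index are
  deliberately excluded (NP-complete).
- No weighted, directed or disconnected-graph variants.
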