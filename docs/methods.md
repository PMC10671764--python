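# Methods

## Compression codec

The compressor is deliberately minimal: a cyclic Burrows–Wheeler transform
followed by run-length encoding, with no move-to-front, entropy coding or
sentinel character. The cyclic variant (sort all n rotations, keep the last
column F and the 0-based rank s of the original rotation) is chosen over the
sentinel variant because the distance below depends on the compressed sizes
of concatenations, and a sentinel would contribute alphabet-dependent
artifacts. For periodic inputs the rank is the smallest sorted index holding
the original rotation; inversion uses stable LF-mapping and is insensitive
to that choice.

Rotation sorting uses prefix doubling (Manber–Myers) on numpy integer
arrays: O(n log n) lexsort rounds, comfortably handling multi-megabase
inputs; strings of ≤ 48 characters take a plain Python sort instead. The
exhaustive and sampled agreement of this sorter with a naive
rotation-enumeration oracle is part of the test suite.

The serialization is `decimal(s)` then `decimal(count)+symbol` per run, an
explicit count even for single-character runs. One octet is one serialized
character, so a run costs `digits(count) + 1` and the total cost is
`digits(s) + Σ (digits(count) + 1)`. This convention reproduces the
calibration values 7 (`BANANA` → `32N1B3A`) and 11 (`BANANACANADA` →
`61D3N1C1B6A`) exactly; `CANADA` costs 9. Multi-digit counts cost extra
octets — that is the declared cost model, not an accident. The serialized
text is ambiguous to parse in general because the rank's digits abut the
first count's digits; `parse_rle(text, n)` resolves the split using the
known sequence length and refuses genuinely ambiguous input.

## Normalized compression distance

Two denominator dialects are exposed and never conflated:

- `max` (default): `(Cxy − min) / max` — the standard NCD form;
- `min`: `(Cxy − min) / min` — the variant under which the codec's costs
  (7, 9, 11) give the calibration value 0.57 for BANANA/CANADA.

This codec is not perfectly symmetric in concatenation order (C(xy) and
C(yx) can differ by a few octets), and C(xx) is small but nonzero. Rather
than hiding either fact, matrices are symmetrized by averaging both orders,
the diagonal is stored as computed, and `metric_report` performs an
exhaustive ordered-triple scan reporting the maximum self-distance, the
maximum pre-symmetrization asymmetry and the triangle-inequality violation
fraction. On the simulated recovery dataset the violation fraction is zero
and the largest self-distance is ≈ 0.02; these are measured properties, not
assumptions.

For unrelated uniform random sequences d ≈ 1 (the concatenation compresses
like two independent strings), while for near-copies d ≈ 0 (rotations of
the two halves interleave and double the run lengths). That separation is
the entire premise of the clustering stage.

## Clustering pipeline

Input is a labeled symmetric distance matrix; all stages are deterministic
with lexicographic tie-breaking, permutation-equivariant, and scale-free
(multiplying the matrix by a constant rescales every area and threshold
consistently).

1. **Triangle filter** (`sigma_filter`, default 2.0 sd). Every unordered
   triple is a triangle with Heron area A; triangles with
   A > mean + sigma_filter × sd are outliers, one-sided because only large,
   deformed triangles (mixing near and far points) indicate spurious edges.
   An edge survives iff it belongs to at least one non-outlier triangle.
   Non-metric triples (negative radicand) clamp to area 0 and are counted.
   Note the statistics include the outliers themselves, so the rule only
   bites when deformed triangles are a minority — the intended regime of
   tens of sequences; in tiny symmetric toys (e.g. congruent triangles
   everywhere) the filter passes everything and later stages separate.

2. **Neighborhood pruning** (`knn`, default 1). An edge (u, v) survives iff
   (a) mutual-kNN: each endpoint is among the other's knn nearest retained
   neighbors; or (b) it is some node's single nearest retained-neighbor
   edge, so pruning never isolates a connected node; or (c) it is a
   scale-consistent relative-neighborhood edge: no third point lies in the
   closed lune of both endpoints (with at least one strictly closer), and
   the edge is at most twice the larger of the endpoints' nearest-neighbor
   distances. Clause (c) exists because a bare mutual-kNN skeleton
   fragments elongated or mildly substructured clusters: genuine internal
   bridges must reach the boundary-detection stage, which sees component
   structure, rather than being cut by a purely local rule. The scale gate
   (factor 2; the factor is the only non-scale-free-looking constant and is
   in fact a ratio, hence scale-free) stops the relative-neighborhood
   clause from retaining the single minimal link between well-separated
   groups, which by definition has no witness but is far longer than
   either endpoint's neighbor scale.

3. **Local-minima partitioning.** Within each connected component, a node
   is minimum-eligible iff no graph neighbor has a strictly smaller mean
   distance to the component. Adjacent eligible nodes with exactly equal
   means merge into one plateau — without this, any exact-tie configuration
   (equidistant points, symmetric pairs) would declare every node a minimum
   and shatter; with it, such configurations remain single clusters. If a
   component holds ≥ 2 plateaus it is split by graph Voronoi: each node
   joins the plateau with the smallest shortest-weighted-path distance
   (ties to the lexicographically smallest plateau label), sub-components
   are re-examined with freshly computed means, and the process iterates to
   a fixpoint.

4. **Singletons and recall.** Components of size 1 are singletons. The full
   pipeline is re-run exactly once on the singleton submatrix, and any new
   clusters of size ≥ 2 are appended — so a coherent group whose triangles
   were all flagged in the first pass (e.g. a distant pair next to a large
   tight cluster) is recovered.

5. **Representatives and auto-correction** (`tie_tol` 1e-9,
   `multiset_max` 3, `max_cycles` 5). A cluster's representative multiset
   contains every member whose summed distance to the other members is
   within `tie_tol` of the minimum; distance from an element to the
   multiset is the distance to its nearest member (zero for members of the
   multiset). A multiset larger than `multiset_max` marks a diffuse,
   overgrown cluster: it is deleted and its members are reassigned to the
   surviving cluster with the nearest representative multiset (or become
   singletons if none survives), cycling to a fixpoint or `max_cycles`.
   `multiset_max = 3` tolerates ordinary near-ties while catching clusters
   whose "center" is effectively everywhere. A backward-pass API hook
   (accept/reject through re-running `auto_correct` with edited
   clusterings) replaces interactive expert feedback; the shipped pipeline
   is fully automated.

**Tree export.** Members of each cluster are agglomerated by average
linkage on the distance submatrix, clusters by average linkage on the mean
pairwise distance between representative multisets, singletons attach at
the root; node heights are half the merge distance (ultrametric display).
This is a visualization of the clustering, not a phylogenetic estimate.

## Pentamer proximity statistic

Given the pentamer set of the ancestral-ring head, O counts sliding-window
occurrences over P = n − 4 windows (all n on a circle in circular mode) and
z = (O − E)/σ with E = P·p and σ = √(P·p·(1−p)). Two modes:

- `printed`: the published constants exactly — ten pentamers with p = 9/1024
  (the source text says nine but prints ten; both are preserved verbatim so
  published values can be approached);
- `consistent`: p = |set|/1024, used for every statistical property test.

The binomial σ understates the true spread: the set is a chain of shifted
pentamers (nine members have their own one-step successor in the set), so
occurrences clump, and exact enumeration of overlap-compatible pairs at
lags 1–4 gives Var(O) = 1.563 × P·p·(1−p), i.e. the null sd of z is 1.250,
not 1. The test suite verifies the Monte-Carlo sd against this analytic
value; users comparing z-scores between sequences are unaffected (the
inflation is a constant factor), but absolute tail probabilities computed
from a standard normal would be anti-conservative.

Degenerate matching (each pentamer also matching its purine↔purine,
pyrimidine↔pyrimidine swapped image, R = A/G and Y = C/T) is off by
default. The ring constant is stored both exactly as printed (23 bases,
containing one anomalous T) and as the derived 22-mer with that T removed;
every ring-based operation takes the ring as an explicit argument.

AL-pair statistics translate each of the ring's n circular codon offsets
with the standard genetic code and emit every ordered offset pair at
circular span 1..12 (n × max_span pairs; STOP rendered `*`). A protein's
successive residue pairs are scored against the distinct unordered AL pairs
under a binomial null with p = distinct pairs / 210 (unordered amino-acid
pairs with identity). This null treats all 210 pairs as equiprobable, which
is a simplification (identity pairs are rarer under uniform residues);
consumers needing exact calibration should use the Monte-Carlo route shown
in the tests.

## Evolution simulator

The simulator emulates clades radiating from independent uniform-random
ancestors under eleven classical operators (definitions in the module
docstring — the disambiguation of inversion = reverse complement,
symmetrization = mirror, palindromization = append reverse complement is
this package's, as the motivating literature names but does not define
them). Per descendant, each operator fires Poisson(rate) times in a
randomized order; crossing over recombines with a fresh copy of the
ancestor so lineages stay inside their clade.

Default regime (chosen once as a moderate structural-variation setting, and
stated here as the package's study condition): 3 ancestors × 8 descendants,
20 kb genomes, segment lengths uniform in 50–500 bp, and per-genome event
means of 100 point mutations (~0.5% of sites), 2 each of translocation,
insertion, deletion, transposition, inversion and repetition, 1 each of
symmetrization, palindromization, circular permutation and crossing over.
Under these defaults the mean within-clade NCD is ≈ 0.27 versus ≈ 1.00
between clades, and the full pipeline recovers the clades exactly
(ARI = 1.0 on the seeded recovery dataset).

What the simulator does *not* emulate: realistic base composition or GTR-
style substitution heterogeneity, selection, coalescent branch lengths,
horizontal transfer between clades, or repeat families predating the
ancestors. Passing recovery tests therefore demonstrates that the codec +
clustering chain detects shared descent signal under structural and point
variation — not that it resolves real taxonomies, which additionally face
compositional convergence and much deeper divergence.

## Numerical and interface choices

- All randomness flows through explicitly seeded `numpy` generators; fixed
  seed ⇒ byte-identical FASTA, JSON and Newick outputs.
- Matrix symmetrization precedes clustering; clustering reads off-diagonal
  entries only and treats d(member, itself-as-representative) as 0.
- Degenerate inputs: empty strings are rejected by the codec; n < 3
  matrices skip the triangle filter with a warning; a window longer than
  the sequence yields an empty profile with a warning; deletion never
  removes an entire genome.
- PHYLIP matrices are written with 6 decimal places (round-trip within
  1e-6); FASTA round-trips exactly.
- Problem sizes in the test suite (24 × 20 kb recovery, 200 × 10 kb null
  calibration, exhaustive ACGT oracle to length 8) were chosen as the
  smallest sizes at which each property is meaningfully exercised.

## Known limitations

- The RLE octet cost grows ~1.5n on random DNA (run counts are mostly 1),
  so this codec measures repeat/motif sharing, not entropy; distances
  between unrelated sequences saturate near 1 quickly.
- The min dialect can exceed 1 and is provided for calibration
  compatibility; use max for analysis.
- The clustering has no notion of hierarchical nesting: clades with strong
  internal substructure are kept whole by design (bridges + boundary
  detection), which may under-split genuinely hierarchical data; lower
  `sigma_filter` or raise `knn` to probe finer structure.
- z-scores in `printed` mode use the printed p = 9/1024 with a 10-pentamer
  set and are therefore slightly inflated by construction; use
  `consistent` mode for self-consistent statistics.
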