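# Methods

## The model in one paragraph

Formaldehyde cross-linking, restriction digestion and religation turn 3D
proximity into ligation products; paired-end sequencing of such a library
from a *mixed* population yields read pairs that are overwhelmingly
intra-cellular. Everything in this package follows from that single fact:
a contact matrix over genome bins shows one dense diagonal block per
replicon (plus inter-replicon contacts for co-resident molecules), a
contact graph over contig chunks decomposes into one community per genome,
and shortest-path distance geometry on inverse contact frequencies places
each genome as a separate body in space — circular chromosomes as closed
rings.

## Coordinate model (genome_digest)

Coordinates are 0-based, half-open throughout. An enzyme is (site, cut
offset); matching is on the forward strand (the classic 3C enzymes HpaII
C^CGG, DpnII G^ATC, HaeIII GG^CC are palindromic, so nothing is lost), all
site occurrences are cut including overlapping ones, and `N` never
matches. On a circular replicon, sites spanning the origin are found by
scanning the sequence extended by `|site|−1` bases; with k ≥ 1 cuts a
circle yields k fragments, the last wrapping the origin. Digesting a
rotated circular sequence yields the same multiset of fragment lengths
(property-tested). Bins group fragments either in runs of N fragments or
by `floor(fragment_start / width)` for a fixed genomic width; a read is
assigned to the fragment containing its 5′ mapped position and inherits
that fragment's bin, so bins never span replicons. On uniform random DNA
HpaII cuts every ~256 bp, i.e. ~4 000 fragments/Mb.

## The simulator (sim_meta3c)

The generator emulates the statistical structure of a mixed-community 3C
library, not its biochemistry:

* **Genomes** are i.i.d.-uniform random DNA (uniform GC; no composition
  bias is modeled). Planted features overwrite sequence in place so
  replicon lengths stay fixed: a segmental duplication copies a source
  interval into a target locus (e.g. an F′-like plasmid), shared repeats
  insert an identical cassette into several species.
* **Contigs** are contiguous genome slices drawn uniformly in
  [0.5, 1.5]×N50-target (or exact tiles), walking whichever replicon has
  most sequence left so species deplete evenly; with probability
  `p_chimeric_join` a contig concatenates half-slices from two species.
* **Pairs** (defaults in `LibraryConfig`): a fraction `p_regular = 0.8` are
  shotgun-like inserts (Normal(600, 100) bp, inward orientation) — the
  regular-pair fraction observed when no religation enrichment is
  performed. The rest are religation products whose genomic separation is
  drawn from `P(s) ∝ s^−α` with `α = 1.0` by default between a floor of
  500 bp (≈ the resolution limit of one restriction fragment; the source
  experiments never report their empirical exponent, so α is a free
  parameter, recoverable to ±0.1 from 10⁶ pairs by log–log regression) and
  the replicon span; circular replicons use circular distance
  min(|Δ|, L−|Δ|), which is what produces the counter-diagonal of circular
  contact maps and the ring closure in 3D. Within a multi-replicon
  species, `p_trans_replicon = 0.2` of religation pairs join two replicons
  uniformly — chosen a priori as the order of inter-replicon contact
  fractions seen in chromosome-capture data of co-resident bacterial
  replicons; it is the knob that lets a secondary chromosome or plasmid be
  pooled with its host. Cross-species chimeras occur with
  `p_chimera = 0.0037` (the measured background of a controlled
  three-species experiment), uniform over abundance-weighted species
  pairs — ligation in solution is concentration-driven and no finer model
  is available.
* **Duplication collapse**: reads from a planted second copy are remapped
  onto the source interval, emulating a mapper facing two identical
  copies. This single mechanism produces all three F′ signatures at once:
  2× coverage of the source interval, plasmid↔chromosome contact
  enrichment, and the correlation shift at the boundaries.
* All draws come from one `numpy` generator; a seed makes every output
  byte-identical. Truth labels (species/replicon/interval per contig
  segment and pair end) ride along in separate columns and are never read
  by inference code.

What the simulator does *not* model — sequencing errors, GC/mappability
bias, repeat-induced mismapping beyond the planted duplication, real
assembler behavior — bounds what green tests mean: they validate the
algorithms under the stated statistical assumptions, not performance on
real libraries.

## Contact maps (contact_map)

PCR duplicates are rows identical on both (ref, pos, strand) ends after
canonical end ordering; one representative is kept. The raw matrix counts
each pair once (both triangles mirrored; self-bin pairs on the diagonal),
so matrix mass equals accepted pairs. **SCN** divides each column by its
sum, each row by its sum, then averages with the transpose, and repeats
until max |row/col sum − 1| < tol (default 1e−6, max 100 iterations —
typically < 20 are needed; symmetrization sits inside the loop so the
criterion holds for the matrix returned). Empty bins cannot be normalized:
they are dropped, recorded, and the drop iterates until the support is
stable. Non-convergence reports the achieved deviation rather than
raising. The diagonal is kept during SCN (a flag on downstream consumers
excludes it where self-contacts are uninformative). The Pearson map
correlates full rows by default; an `exclude_diagonal` option computes
pairwise-complete correlations without the two self columns. Constant
rows get correlation 0 and a flag. Masking removes whole bins overlapping
the given regions; masking commutes with matrix construction on
bin-aligned regions (tested).

## Binning (binning)

Contigs longer than 2.5 kb are split into `floor(L/2500)` equal chunks
(±1 bp) so that long contigs — which collect more contacts merely by
length — contribute proportionally many nodes instead of one heavy node;
edges are raw pair counts (no length normalization needed after
chunking). Louvain is delegated to networkx's implementation (resolution,
seeded node order); `repeats` restarts keep the best-modularity partition.
Tests cross-check planted-partition recovery against python-igraph's
independent multilevel implementation and against exhaustive two-partition
enumeration on small graphs. Chunk communities are reconciled per contig
by length-weighted majority; agreement < 0.5 or a tie leaves the contig
unattributed.

**Resolution default.** On decay-dominated contact graphs, modularity at
r = 1 splits each genome into pure ~250 kb arc communities (a ring-lattice
effect). One-community-per-genome is a broad plateau — r ∈ [0.03, 0.5] on
the default mix, with identical purity-1.0 partitions across the plateau —
so the pipeline default is r = 0.3. The generic `PartitionParams` default
stays r = 1 for ordinary community-structured graphs (the
planted-partition benchmark).

## 3D reconstruction (structure3d)

Edges are `1/contact` for every positive off-diagonal entry; all-pairs
shortest paths are computed with scipy's csgraph routines (any algorithm
meeting the all-pairs contract is acceptable; tests pin exact agreement
with brute-force path enumeration). Classical scaling: eigendecompose
`−½ J D² J`; coordinates are the three leading non-negative eigenpairs
scaled by √λ. Numerical choices: eigenvalues below 1e−12·λmax are
truncated to exactly zero (a planar input must embed exactly planar);
negative eigenvalues (non-Euclidean D) are truncated and their magnitude
reported; each axis is flipped so its third moment is non-negative, fixing
the reflection ambiguity for reproducible output. Stress is
‖D − D_emb‖_F / ‖D‖_F; it is 0 (to tolerance) exactly when D is realizable
in ≤ 3 dimensions. Three points suffice for an embedding; fewer raise.
Disconnected maps are embedded per component, largest first; components
under 3 bins are reported and skipped. Ring diagnostics report
max-gap/median-gap and closure-gap/median-gap along the genomic bin order;
a well-sampled circular chromosome closes (closure ≈ median adjacent gap)
while a linear one leaves a closure gap tens of medians wide.

## Feature analyses (features)

Coverage counts both pair ends per bin and normalizes by the median over
non-empty bins (median of reported values is exactly 1). Duplication calls
are maximal runs of ≥ 3 bins at normalized coverage ≥ 1.6 — between the
single-copy and two-copy levels; both knobs are exposed. Contact profiles
average the query rows of the SCN matrix with query columns excluded.

**Correlation shift.** The curve is, per non-query bin j, the Pearson
correlation between the query's profile and bin j's contact row over bins
outside the query and a ±5-bin guard window (the guard size is a
parameter; nothing in the source material fixes it). For *localization*
the curve alone is too blunt: neighboring bins share the distance-decay
trend, which smears the correlation a few bins past a duplication
boundary, whereas the query's own contact profile steps bin-sharply there.
The change-point is therefore found on the sum of the winsorized (±5)
robust z-scores of both curves, scanning all ≥ 3-bin segments for the
maximal balanced mean-shift statistic
`(mean_in − mean_out)·√(n_in·n_out/n)`, and is reported only when that
statistic exceeds the 99th percentile of its own permutation null (200
permutations, seeded) — no fixed contrast constant. On planted 140 kb
duplications at 10 kb bins the boundaries land within 1–2 bins.

## Evaluation (evaluation)

Breadth of coverage is the per-replicon interval-union of contig source
intervals over replicon length (with a length-weighted species rollup);
purity is the length fraction of a community from its dominant species,
chimeric contigs excluded from purity and ARI but counted separately (by
count and by length); N50 is the largest L with Σ(lengths ≥ L) ≥ total/2.
Fractions are reported to 3 decimals with counts alongside.

## Pipeline (pipeline, cli)

One global seed; each stage derives `(seed·1000003 + crc32(stage)) mod 2³¹`
so stages are independently reproducible. Every stage writes plain-text
artifacts (FASTA/TSV/JSON) plus a manifest with parameter hash and output
checksums; re-running a completed stage is a no-op, and two runs with the
same seed are byte-identical across directories (manifests and config
record the output path and are the only files that differ). Default
problem sizes — three species totalling 3.5 Mb, 2×10⁶ pairs, 10 kb bins
(~350 bins, ~1 300 chunks) — are desk-scale choices that keep a full run
in minutes while leaving every per-bin statistic well sampled.

## Known limitations

* The simulator's uniform-DNA assumption makes restriction sites Poisson;
  real genomes have site clustering and unmappable regions, so empty-bin
  handling is exercised less than it would be on real data.
* SCN corrects multiplicative per-bin biases only; explicit-factor
  corrections (GC, mappability) are out of scope.
* Community detection inherits modularity's resolution behavior; the
  species plateau was characterized on the default mix and should be
  re-examined for communities with very uneven abundances.
* The 3D embedding is a single consensus structure; no ensemble or
  polymer-model fitting is attempted.
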