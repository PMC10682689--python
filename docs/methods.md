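# Methods

## Data model

A tree sequence is held as a `TableBundle`: a sequence length `L`, a node
table (time in generations before present, population id or -1, sample
and census flags), an edge table `(left, right, parent, child)` and a
population table.  Coordinates are 0-based, half-open and real-valued;
node and population ids are row numbers.  Structural invariants: `left <
right`, edge intervals inside `[0, L]`, strictly `time(child) <
time(parent)` (zero-length branches are rejected), per-child parental
intervals pairwise non-overlapping (each genome position inherits from at
most one parent), and a canonical edge order ascending by `(parent time,
parent id, child id, left)` — the standard tree-sequence sortedness
requirement.  `validate_tables` reports every violation rather than
raising, so a user sees all problems at once; consumers that need sorted
edges sort internally and log instead of rejecting.

The text dialect is tab-separated with a header row, using the column
names of tskit text dumps (`id/is_sample/time/population` for nodes,
`left/right/parent/child` for edges) plus an `is_census` node column and
a `#sequence_length=<L>` metadata line in the edge file; extra columns
are ignored on read so tskit dumps load directly.  Floats are written
with `repr`, the shortest exact representation, so
`read(write(x)) == x` holds field-for-field.

## The single-pass linking algorithm

Query: samples S, ancestors A, disjoint and non-empty.  Semantics: for
every position x and sample s, x is assigned to the first member of A on
the child-to-parent path from s in the local tree at x (the most recent
ancestor); if the path ends first, x is unassigned.  Supplying both an
ancestor and its own ancestor therefore links everything to the younger
one — the deliberate disambiguation when lineages pass through more than
one candidate ancestor, which matters whenever there is ongoing
migration between the populations of interest.

Implementation: each sample starts owning `[0, L)` as one segment; edges
are processed in canonical order, so all edges into a parent are seen
before any edge out of it (child time < parent time guarantees this).
For edge `(l, r, p, c)`, the parts of c's segments inside `[l, r)` move
to p; if `p ∈ A` they are emitted as output instead of retained, so
propagation stops at the most recent ancestor.  Per-node state is a
mapping sample → sorted disjoint interval list; at any instant each
genome position of a sample sits at exactly one node, so merging into a
destination list is a two-way merge that only needs to coalesce
exactly-adjacent pieces.  A node's state is dropped as soon as its last
edge as a child has been processed (whatever remains has reached a root
and is unassigned), bounding memory.  Finally, emitted pieces with equal
(sample, ancestor) that touch exactly are merged and rows are sorted by
(sample, left, ancestor), making the output minimal and canonical —
which is also why splitting any edge in two leaves the output unchanged.

Ancestors at heterogeneous times are accepted with a logged warning
(single-census queries are the recommended use); a sample that is itself
internal (ancestral to another sample) is traced independently and
flagged in the log.  Samples ∩ ancestors is an error: self-ancestry is
ill-posed here.

`coverage_report` complements the links with the exact per-sample
decomposition of `[0, L)` into assigned and unassigned intervals;
endpoints are reused unchanged, so assigned + unassigned lengths equal
`L` exactly in floating point.

## The per-tree reference implementation

`local_ancestry_naive` defines correctness.  Local trees are
reconstructed with the standard two-index sweep (edges sorted by left
for insertion, by right for removal); breakpoints are the distinct edge
coordinates and the intervals tile `[0, L)` exactly.  For each interval
and sample it climbs parent pointers to the first member of A, then
concatenates runs of equal assignment across intervals.  The module
optimises for clarity, not speed — O(edges × trees) — and its agreement
with the single-pass engine, row for row on hand fixtures and hundreds
of simulated tree sequences, is the central test of the package.  Both
are additionally cross-checked against tskit's independent C
implementation on msprime coalescent simulations with census events.

## Tract post-processing

`annotate_populations` adds the ancestor's population (`p_a`) to each
link row (error if an ancestor is unlabelled); `squash` sorts per sample
by left and merges runs that share a population and touch exactly,
dropping the ancestor column.  Unassigned gaps are never bridged — this
preserves the coverage decomposition and makes squash idempotent and
exactly length-preserving per (sample, population).  The squash is
verified against an independent position-sweep repaint oracle.  BED
export writes one "chromosome" per sample haplotype; non-integer
coordinates are an error unless rounding (floor start, ceil end) is
explicitly requested, because silent rounding corrupts tract lengths.
Diploid pairing/phasing presentation is out of scope.

## The Wright–Fisher simulator

Forward-time, haploid, discrete generations `G .. 0`, constant
population sizes, no simplification: every genome of every generation is
a node, so census semantics are exact by construction — the census nodes
at generation g are all genomes alive then, and every sample lineage
passes through them (which is why full-census coverage equals `L`
exactly, a conservation law the tests assert).  Transmission: each child
draws a parent population (backward migration matrix row, or the
admixture proportions at the pulse generation), then two uniform parent
genomes from that population, and recombines them with Poisson(ρl)
crossovers at uniform integer positions in `1 .. l-1` (deduplicated);
segments alternate between the two parents.  Integer breakpoints make
BED export lossless.  All draws flow through one `numpy` generator
seeded from `SimParams.seed`; identical parameters and seed give
byte-identical written tables.

The admixture pulse founds the destination population at generation
`g_adm`: its genomes at `g_adm - 1` draw parents from the sources with
the stated proportions, and the destination has no genomes at or above
`g_adm`.  Source populations persist to the present.  Migration into the
destination from other populations is rejected at validation to keep the
scenario well-posed.

The demonstration scenario is two sources of 20 haploid genomes with
symmetric 1% migration, a 50:50 pulse at generation 10 into an admixed
population of 20, `G = 30`, `l = 100 kb`, `ρ = 1e-5` (so ρl = 1
crossover per meiosis — a human-chromosome-like rate at desk scale), 10
samples, census at generation 11.  These sizes keep a full simulation
plus both extraction engines well under a second while leaving enough
recombination (~10–20 tracts per genome at the census) for the
population-level behaviour to be visible.

What the simulator does *not* emulate: diploidy and pedigrees,
selection, mutation/sequence data (ancestor linking never touches
genotypes), variable recombination maps, and coalescent-scale deep
histories.  Passing tests therefore demonstrate correctness of the
extraction algebra on genealogies with the right structure (recombination
breakpoints accumulating linearly in time, migration-induced label
mixing), not realism of any particular demographic fit.

## Scaling check

The expected tract count at census depth t is `1 + ρlt`.  The tests
regress the mean per-sample link-row count on t ∈ {5, 10, 20, 40} in a
single population of 500 (large, to keep two adjacent segments from
landing in the same ancestor and merging), ρl = 0.5, 50 sampled genomes
per replicate, and require the slope within ±25% of ρl and the intercept
within ±0.5 of 1.  Measured values sit near 0.46–0.50 and 0.75–1.3
across seeds: slightly below the nominal slope, as expected, because
same-ancestor coalescence and breakpoint collisions remove a small
fraction of potential segment boundaries.

## Numerical choices

Interval arithmetic is exact: endpoints are only ever copied, compared
or reused, never recomputed by addition, so equality tests (adjacency
merging, coverage accounting, round-trips) are safe in floating point.
Tie-breaking among edges with equal parent time follows the canonical
sort key; correctness cannot depend on it because equal-time nodes are
never ancestral to one another.  Degenerate inputs: empty edge tables
are valid (everything unassigned), empty link tables squash to empty
tables, a bundle with one node and no edges round-trips.

## Known limitations

- The linking pass holds segment lists for every node on a sample-to-
  ancestor path until the node's last child edge is seen; for very deep
  censuses with many recorded ancestors memory grows faster than the
  output size.  A garbage-collection scheme for stale deep-time state is
  a possible future optimisation.
- One census query per pass; querying several census times re-runs the
  pass (the simulator records several censuses in one run, so this is
  cheap at desk scale).
- The text dialect reads tskit text dumps but ignores mutation/site/
  individual tables; the binary `.trees` format is not read.
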