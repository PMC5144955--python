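# Methods

## Genome model and event algebra

A genome is a set of named chromosome arms, each an ordered list of oriented
genes read centromere → telomere (index 0 proximal). Coordinates are arm-local
0-based ordinals; a breakpoint is a cut *after* ordinal *i*, with *i* = −1
meaning "before the first gene". This half-open convention makes segment
arithmetic unambiguous: a reciprocal translocation at cuts (c₁, c₂) exchanges
the distal segments `arm1[c1+1:]` and `arm2[c2+1:]`; an inversion at (b₁, b₂)
with b₁ < b₂ reverses `arm[b1+1:b2+1]` and flips orientations. Inversions and
translocations at fixed cuts are involutions, and translocation, inversion
and transposition conserve the gene-id multiset — both properties are tested.

Orientation is tracked even though the marker-scan inference is
orientation-agnostic, because orientation flips are the observable trace of
intragenic and small inversions (e.g. the inverted *HLH* copy in the barley
panel). A third orientation value `?` exists for curated fixtures where a
fragment's orientation is experimentally undetermined; simulation output
never produces it.

Gene loss is a deletion event; paralogy is modelled as distinct gene ids
sharing a `family_id` (the PMEI-like genes form one family). Transposition is
modelled as single-gene relocation: the event record carries the moved gene
as payload and the insertion cut. The observed transpositions in the study
system (*HLH*, *FBA1*, *PLC3*) are single-gene moves, and a multi-gene block
move is not addressable with the two breakpoint slots an event carries; block
transpositions are out of scope.

## Synthetic data: what it emulates, and what it does not

The generator evolves a rearrangement-free ancestor (default 2 arms × 20
genes, all `+` orientation) along a user-supplied Newick tree. Event counts
per branch are Poisson with branch length as exposure (rate default 0.5 per
unit length — an arbitrary but fixed neutral clock; no rearrangement-rate
estimates exist for the study clade), or an explicit per-branch schedule for
controlled experiments. Event parameters are sampled uniformly over positions
that leave affected segments non-empty; infeasible types renormalize. Event
type weights default to translocation 0.20, inversion 0.30, transposition
0.15, deletion 0.15, duplication 0.10, TE insertion 0.10, loosely reflecting
the prominence of inversions among plant rearrangements.

Marker tables are emitted one marker per reference gene (markers ≡ genes;
many-markers-per-gene is a non-goal). A query hit set is the set of arms
carrying a member of the marker's gene family. Noise mimics homology-search
artifacts: with `detection_miss_rate` a hit set is emptied (missed homolog),
with `paralog_hit_rate` one uniformly chosen extra arm is added (off-target
paralog hit). Band counts (Poisson mean 9, +1) stand in for BAC-fingerprint
consensus bands and feed the 1.5 kb/band physical-size rule.

Junction sequences are synthesized to a segment model's total length: an
A/T-run-free background at the configured GC (default 0.44, a cereal-like
value), then `round(enrichment × length / 1000)` homopolymer tracts of
length 6 + geometric(p = 0.5) excess placed at uniform non-overlapping
positions with non-identical guard bases, so the realized tract count is
exact and the realized per-kb frequency is within rounding of the target.
The default enrichment, 18.4/kb, is the density reported for a sequenced
translocation junction and is used as a realistic setting — synthesized
sequences share no other feature with real junctions (no TE nesting, no
compositional domains, no mixed A/T tracts), so round-trip tests validate
the scanner and generator, not any claim about real wheat sequence.

Everything is deterministic in the seed: named substreams (`[seed, k]`, with
the profile-noise stream additionally keyed by arm id) keep experiments
independent, and all writers are byte-stable.

## Breakpoint inference

The transition scan works per query column of a location-profile table.
Markers hitting every arm of a constant homoeologous background (e.g. 5BL and
5DL behind a 5AL→4AL transition in hexaploid wheat) carry no positional
signal, so the default candidate set is the *variable* arms of the column —
arms present in some but not all non-empty hit sets; callers can pass the
candidate arms of the homoeologous groups under test explicitly (necessary
when, as in rye, the 4L-derived material resides on a group-7 arm). Per
marker, the consensus is the single candidate arm among its hits; empty,
non-candidate and multi-candidate (ambiguous) hits are skipped and do not
interrupt runs. A breakpoint is called between two maximal runs of distinct
consensus arms when both runs have ≥ `min_run` markers (default 2): one
discordant marker never calls a breakpoint. Ties can never elect an arm —
conservative by construction. The call records flanking markers, their full
hit sets, the run consensus arms, and the gap's physical size when every
marker in it has a band count.

Gene-level refinement (`delimit_by_gene_pair`) classifies annotated genes
inside an interval by the side-specific arms of its flanks and narrows to the
last proximal-side gene before the first distal-side gene, returning the
interval unchanged when the annotations are concordant or not a clean
transition.

Block chaining is greedy left-to-right over the shared genes: a block extends
while the outgroup index steps by +1 (same strand) or −1 (reversed); length-1
blocks are kept and flagged as possible transpositions rather than merged.
A breakpoint coincides with an ancestral block junction when its cut-site
set `{p..d−1}` intersects the boundary gap's — i.e. no marker separates them.
Intersection rather than strict containment matters in practice: a
lineage-specific transposed gene absent from the outgroups widens the
apparent block gap beyond the breakpoint gap without breaking the
coincidence.

## Event classification and recurrence

Classification combines calls and blocks per reference arm. Two arms whose
single calls exchange consensus arms (X's distal = Y's proximal and vice
versa) yield one reciprocal translocation; matching is by arm identity, not
homoeologous group number, because a translocated segment may reside on any
arm of the query (rye's 4L material is on 7RS). For intra-arm structure,
relocated single genes are separated from the collinear spine iteratively:
a singleton block is in place if its outgroup position falls strictly between
the envelopes of the non-singleton blocks around it (both arms are read in
the same centromere→telomere frame, so the spine is forward); otherwise the
most-displaced singleton is removed and the remaining walk re-chained with
rank-compressed positions until stable. Removed genes are transpositions;
reversed spine blocks of ≥ 2 genes are inversions; unpaired calls are
reported `unclassified` with their evidence.

Recurrence is quantified two ways on the carrier character (tips 0/1, with
`{0,1}` for species where the rearrangement is not fixed): the Fitch
small-parsimony change count, and the headline statistic, the minimum number
of independent 0→1 origins over ancestral labelings with the root fixed
non-carrier. Origins are counted under irreversibility (no 1→0 edges): a
fixed reciprocal translocation has no realistic reversion path, and allowing
free losses would let a single early gain plus losses explain any carrier
pattern (on the packaged topology it collapses 2 origins to 1). The
losses-allowed variant is exposed as an option. Both routines are verified
against exhaustive-labeling enumeration on random trees of ≤ 8 tips.

Breakpoint reuse compares two intervals via ortholog ids on a common
reference order: `shared` iff both flank pairs are identical, otherwise
`distinct_nearby` when the interval midpoints are within `nearby_threshold`
genes (default 5 — chosen so that 5L breakpoints a few genes apart, as in
wheat vs rye, count as nearby while unrelated intervals do not), else
`distinct_far`. Distances round half-up to whole genes.

## Junction accounting and tract scanning

A junction model is an ordered list of (label, class, length,
lineage-specific) segments; derived lengths subtract segment classes (and
optionally lineage-specific segments) from the total. The packaged model of
the sequenced 4AL junction uses the published component lengths (2559 bp
total; 706 and 235 bp 3′ UTRs; 265 bp MITE); the positions of the MITE and
the *T. monococcum* tandem duplication inside the core are schematic because
only the lengths were published.

Poly(dA:dT) tracts are maximal runs of A, or of T, on the forward strand with
length ≥ 6 bp; an A-run on one strand is a T-run on the other, so
forward-only A and T runs capture both orientations, and mixed A/T runs
(`ATAT…`) do not count — the term denotes homopolymeric dA:dT. `N` breaks
runs and still counts toward length for per-kb normalization. Density uses
tumbling (non-overlapping) 100-bp bins; a tract spanning a boundary
contributes per-base overlap to each bin, so the bin sum always equals the
total tract length. Frequency is tracts × 1000 / sequence length.

## Validation experiments and their scope

The recovery experiment simulates one reciprocal translocation per trial
(2 arms × 20 genes), with cuts drawn uniformly among positions leaving at
least `min_run` markers on each flank — a cut with no flanking run is
undetectable by any marker method, so such cuts measure nothing about the
scan. Noise-free, 100% of 200 trials are bracketed with exactly adjacent
flanks and rearrangement-free columns never produce calls. Under 10% marker
dropout the per-trial (both arms) success rate is typically 93–98% depending
on the seed: the dominant failure is arithmetic, a 2-marker flank losing one
marker (probability 0.19 per such flank) leaves fewer concordant markers
than `min_run` allows calling on. Classifier accuracy is measured on 200
noise-free single-event simulations per type; simulated inversions span ≥ 2
genes and transpositions move a gene ≥ 2 positions, since shorter events are
not distinguishable in gene-order data (a 1-position move is identical to a
2-gene inversion up to orientation).

Problem sizes throughout (20 genes/arm, 200 trials per condition, 500 random
trees, 1000 scanner sequences, 2.5-kb synthetic junctions) keep the full
validation under a few seconds while giving exact-agreement checks no room
to hide: all oracle comparisons demand 100%.

## Known limitations

* Arm-level coordinates only; no nucleotide sequences for whole arms, no TE
  nesting structure (TE-rich stretches are a segment class).
* Transpositions are single-gene; block moves and orientation-flipping
  transpositions are not classified.
* The scan assumes one candidate arm per homoeologous group per query; true
  multi-candidate hits are treated as missing rather than resolved.
* The origin count is a parsimony bound, not a probabilistic estimate; no
  branch-length-aware ancestral reconstruction is attempted.
* The curated fixture's rye and barley gene orders are tentative in the
  underlying study (survey sequence, collinearity assumptions) and are
  flagged as such in the fixture metadata.
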