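# Methods

## Scope and data model

The package analyzes annotated circular mitochondrial genomes of the usual
metazoan type: 13 protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and one
control region (CR), with genes on both strands. The internal model
(`MitoAnnotation`) keeps 1-based inclusive coordinates as GenBank and
published organization tables do; a feature may wrap the circular origin
(`end < start`), and all length/gap arithmetic is modular. Gene names are
canonicalized to a fixed vocabulary (`cox1..3`, `nad1..6`, `nad4l`, `atp6/8`,
`cob`, `trnX` with the Leu/Ser isoacceptors split as `trnL1/trnL2`,
`trnS1/trnS2`, `rrnL/rrnS`, `CR`); labels that cannot be resolved are kept
verbatim and flagged, never dropped. Duplicated genes carry occurrence
suffixes (`trnQ#2`) so gene-order analysis can represent duplications. The
CR is carried as a positional feature but is not counted as a gene (the
37-gene census and strand counts exclude it).

## Composition and skews

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C); both are
scale-invariant and accept counts or percentages. Conventions:

- the whole-genome row is computed on the heavy strand;
- single-gene rows and the class rows (PCGs, tRNAs, rRNAs) are computed on
  each member's transcriptional reading sense, members concatenated in
  annotation order. With four of the thirteen PCGs on the light strand, a
  heavy-strand class computation would invert the sign structure of the PCG
  row relative to what published composition tables show; the reading-sense
  convention reproduces it.
- Ambiguous bases (N) are excluded from both skew terms and from the
  percentage denominator; they are tracked separately in the region size.

Report serialization rounds percentages to 2 dp and skews to 3 dp; internal
values keep full precision.

Adjacency accounting walks consecutive features by start position, wrapping
last→first: `gap = start(next) − end(prev) − 1` (modular), so a k-bp overlap
is gap −k, abutting genes gap 0, and a spacer gap +k. The report exposes the
raw pair list rather than committing to any one published counting rule for
"number of non-coding regions", which varies between papers.

## Codon usage and RSCU

The default genetic code is NCBI translation table 5 (invertebrate
mitochondrial); codon tables come from Biopython. RSCU(c) = n(c) divided by
the mean count of c's synonymous family. Two non-obvious choices:

- stop codons (UAA/UAG under table 5) form their own two-member family, so
  they receive RSCU values like any other family;
- codon counting tallies every in-frame triplet across the PCG set,
  including internal stop triplets, because published mitogenome codon
  tables are built this way (their stop-codon counts exceed the gene
  count). Counting with stops excluded is available via a flag.

Families with zero total usage get RSCU 0 for all members and are flagged.
Reports use the RNA alphabet. Incomplete stop codons (trailing T/TA
completed by polyadenylation) are reported as such by the start/stop
detector rather than being "corrected".

## Ka/Ks (Nei–Gojobori 1986)

Implemented from first principles (the classical counting method that
DnaSP/MEGA expose), not wrapped from another package:

- per codon and position, the synonymous site fraction is s/v where v
  counts one-step changes that do not create a stop codon ("viable") and s
  those that preserve the amino acid; S = Σ s/v, N = 3 − S. Site totals are
  averaged between the two sequences.
- differences are averaged over all d! orderings of the d differing
  positions with equal weights; orderings that pass through a stop codon
  are excluded when at least one stop-free ordering exists, otherwise all
  orderings are used and the pair is flagged.
- pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
  K = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is reported as saturation (rate None),
  and Ks = 0 leaves the ratio undefined rather than infinite.

Codon pairs containing gaps, ambiguity characters or stop codons are
skipped pairwise. Alignment is assumed given (codon-aligned input); the
package does not align. Panel analysis averages all pairwise (or
focal-vs-others) results per gene, excluding undefined ratios with a count.

The implementation is verified against loop-literal brute-force oracles
(all 60 sense codons for sites; all sense-codon pairs for pathways; random
≤5-codon pairs end to end at 1e-12).

## Gene-order analysis

Orders are signed circular token sequences; normalization rotates a
designated anchor (default `cox1`, preferring + orientation) to the front so
circular comparisons are deterministic. The breakpoint distance counts
signed adjacencies (a→b with orientations) of the derived order absent from
the reference, after restricting both orders to their shared token set; it
is zero iff the orders are rotation-equal.

Event detection searches exhaustively over gene subsets of size ≤
`max_moved` (default 3, enough for single-gene and two-gene events while
keeping the search trivial) whose removal makes the orders rotation-equal.
Ties between equally small subsets are broken by preferring subsets with
fewer PCG/rRNA members — tRNA translocations being the common mitochondrial
mechanism — then lexicographically; e.g. the focal rearrangement is
explained equally well by moving `trnL2` or `cox2`, and the tie-break
selects the tRNA. Orientation differences (CR excluded) are reported as
inversions; multiset excess as duplications. Larger events (e.g. an
8-gene block move) are flagged `complex` and reported via breakpoints only.
Reported placements (gene, orientation, predecessor) allow replaying the
translocations onto the reference; the round trip reproduces the derived
order whenever the report is not complex.

**TDRL.** One tandem-duplication/random-loss event duplicates a span in
tandem and loses one copy of each gene; the survivors of the first copy
(in reference order) precede the survivors of the second copy. A derived
span is therefore one-TDRL reachable iff its tokens, indexed by reference
position, split into at most two increasing contiguous blocks —
equivalently the index sequence has at most one descent. (The weaker
condition "decomposable into two increasing subsequences" admits
interleavings such as 2,0,3,4,1,5 that no single loss pattern can produce.)
TDRL never inverts, so any orientation mismatch is an immediate negative.
The span is compared linearly as given; whole-circle callers normalize both
orders to the common anchor first. The criterion is property-tested against
full enumeration of all 2^n loss patterns for random orders of length ≤ 7.

The ancestral decapod and caridean reference orders ship as token strings in
one data file (`data/gene_orders.tsv`), isolated so any transcription
question touches a single place; the two are identical at token level, as
are the orders of the caridean families that retain the ground pattern.

## Synthetic data generator

`generate_genome` lays out the template gene order (default: ancestral
decapod pattern, 38 positional tokens) around a circle with configurable
per-gene lengths (defaults mirror the reference mitogenome, PCGs rounded to
whole codons), a fixed intergenic spacer (default 2 bp), and an origin
placed inside a spacer. Any requested surplus genome length is absorbed by
the spacer upstream of the first feature, emulating an expanded AT-rich
region; a genome length too small for the parts is an error.

Sequence is drawn on the heavy strand from the target base composition
(default A 32.51 / T 31.91 / G 14.24 / C 21.33 percent). PCGs are generated
in reading sense as clean ORFs — ATG/ATA start, no internal stops, TAA/TAG
terminator — and reverse-complemented onto the heavy strand for light-strand
genes (which preserves A+T content exactly). Internal codons are drawn from
a sense-codon distribution; by default that distribution is the
position-independent product of the target base frequencies, iteratively
reweighted (raking) so that the codon marginals hit the target composition
despite the exclusion of stop codons. Residual bias from the fixed
start/stop codons is ≈ +0.2% AT at genome scale, well inside the sampling
band (two binomial standard deviations ≈ 0.75% at 16.3 kb, the tolerance
the tests use; halved bands at 4× length check the 1/√n convergence).
A user-supplied 64-codon weight table overrides the raked default, in which
case realized composition follows the weights, not the composition target.

Rearrangement ops (`translocate`/`invert`/`duplicate`) are applied to the
token order before layout, so generated genomes round-trip exactly through
`order_from_annotation` and event detection.

`evolve_pair` draws a uniform-sense-codon ancestor and applies accepted
point substitutions until a Poisson(n_codons × subs_per_codon) target is
reached (default 0.3 substitutions per codon — low enough that the
Jukes–Cantor regime holds, high enough that Ks is well resolved at 2000
codons): proposals pick a random codon, position and base; stops are
rejected outright, synonymous changes always accepted, nonsynonymous
changes accepted with probability ω. Because NG86 site fractions are
defined by the same viable-change convention, the NG86 estimate recovers ω
with small bias at low divergence (recovery within ±0.05 at ω = 0.2,
n = 2000 is part of the test suite). At ω = 0 the realized Ka is not
exactly zero — pathway averaging over doubly-hit codons contributes
fractional nonsynonymous differences — but is orders of magnitude below Ks.
Panels use a star topology (independent descendants of one ancestor per
gene), which matches how per-gene pairwise averages are computed downstream;
no tree correlation structure is modeled.

What the generator does **not** emulate: real codon-usage bias beyond the
composition target, tRNA secondary structure, indels, rate variation among
sites, strand-asymmetric mutation pressure within genes, and overlapping
genes (generated features never overlap). Tests passing on synthetic data
therefore validate the arithmetic and the estimators under the stated
model, not robustness to those features of real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run on: the 38-row reference
organization table; 16.35 kb synthetic genomes (plus 4× scaled versions for
convergence checks); 2000-codon pairs for ω recovery; a 13-gene × 6-species
simulated panel at 400 codons per gene; 300 random small pairs against the
NG86 oracle and 500 random orders (length ≤ 7) against the TDRL oracle —
sizes chosen so every guarantee is exercised in seconds. All simulation
randomness flows from a single integer seed (`numpy.random.default_rng`);
derived seeds stay below 2^31. Exhaustive event search is capped at
`max_moved = 3`; rounding happens only at serialization (percent 2 dp, skew
3 dp, RSCU 2 dp).

## Known limitations

- Event detection reports one minimal explanation; rearrangement histories
  are generally not unique, and the PCG/rRNA-averse tie-break is a
  parsimony heuristic, not an inference.
- The NG86 estimator inherits the method's known biases (equal pathway
  weights, no transition/transversion weighting, JC correction); it is not
  a maximum-likelihood dN/dS.
- Published tables carry their own internal inconsistencies (e.g. a
  composition row whose printed AT-skew contradicts its printed A%/T%);
  the bundled data preserve the printed values and downstream computations
  recompute from the raw columns.
- GenBank parsing expects annotated records (CDS/tRNA/rRNA features); the
  package does not do de novo annotation, read assembly, alignment, or
  phylogenetic inference.
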