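# Methods

## Character encoding

A ChIP-seq peak track defines a binary state per nucleotide: ON inside a
peak, OFF outside. All coordinates are BED-native (0-based, half-open);
overlapping and book-ended intervals are merged during normalization,
since per-nucleotide ON/OFF status is the only semantics used. Sample QC
follows a per-chromosome completeness rule: a sample is dropped when it
has zero peak intervals on any chromosome of the declared genome layout,
excluding chromosome Y by default (many donors lack it). Because only
peak files are consumed, "missing data" is operationalized as "no peaks
on that chromosome".

The genome is partitioned into atomic segments at the union of all
interval endpoints, so each segment carries one cross-sample state
vector. Identical vectors are collapsed into unique site patterns with
summed bp weights; a segment map retains the decoding back to BED. Tree
length is additive over characters and identical characters have equal
length on every tree, so parsimony on weighted unique patterns is exactly
equivalent to parsimony on the raw per-nucleotide matrix; the test suite
verifies this equivalence (score, per-branch bp tables, decoded
progenitor tracks) against a literal one-character-per-nucleotide run.
Partitioning streams one chromosome at a time, so memory scales with the
number of unique patterns, not genome size. Constant patterns are kept in
the matrix — absolute ON bp per gene is a reported output — but skipped
by the parsimony engine, where they contribute nothing.

## Tree, constraints, branch classes

The cell-type tree is rooted on the branch between the myeloid (M) and
lymphoid (L) progenitors, matching the stem-cell position of the
classical hematopoiesis model; the backbone over the eight cell types is
fixed and each type's samples are constrained to be monophyletic. Edges
strictly inside a type's clade are intra-type (tissue/individual/subtype
variation); all others — type stems and the backbone — are inter-type.
The two root half-edges are reported as the single unrooted M–L branch.

Within-type topologies are inferred, when requested, by random-addition
stepwise insertion followed by TBR swaps (bisect a within-clade edge,
reroot the detached part on any of its edges, reconnect on any remaining
within-clade edge), first-improvement acceptance, iterated to a local
optimum. Constraint-violating proposals are never generated, accepted
swaps never increase the weighted score, and the search is deterministic
given its seed. The search matches the algorithm class of a standard
constrained heuristic search, not any particular implementation's
trajectory.

## Parsimony and MPR resolution

Characters are binary with equal, undirected costs, so pattern length is
computed with the two-state min-cost (Sankoff-style) recurrence, which is
exact for multifurcations; the implementation is vectorized across
patterns. MPR state sets come from the standard up/down decomposition
(cost below a node given its state, plus cost of the rest of the tree).
A single labeling is chosen per pattern in a root-down pass: each node
takes the state minimizing subtree cost plus the parent mismatch; on
ties, ACCTRAN takes the state opposite the parent (changes accelerate
toward the root) and DELTRAN the parent's state (changes delay toward
the tips). Root-state ties resolve to OFF; this makes the direction of a
change on the root branch a reporting convention — for an undirected
character it is not identifiable — and the recovery metric therefore
matches root-branch events by (branch, region) ignoring direction.
ACCTRAN is the default for reporting; DELTRAN is selectable everywhere.
Change costs are fixed at 1/1; asymmetric costs are out of scope.

Per-edge changes are parent-vs-child comparisons of the resolved states;
their bp-weighted aggregation per branch and direction (GAIN = "ON",
LOSS = "OFF") is the per-branch change table. The engine is tested
against exhaustive enumeration of all internal labelings on ≥1,000 random
trees (≤12 leaves, multifurcating): lengths agree exactly and both
resolutions are always members of the enumerated MPR set.

## Annotation and statistics

Changed patterns are classed INTER_ONLY / INTRA_ONLY / MIXED by the edge
classes of their changed edges. TSS distances are measured from the
segment midpoint (configurable to the 5′ end) to the nearest TSS, signed
by gene strand (negative = upstream); equidistant ties go to the
lexicographically smaller gene id. Distances fall into 12 categories —
0–1, 1–3, 3–5, 5–10, 10–100, >100 kb on each side of the TSS — with
half-open, lower-inclusive bands (|d| = 1,000 falls in 1–3 kb; d = 0 is
downstream 0–1 kb). Category fractions are bp-weighted. Segments on
chromosomes without genes are "unassigned" and excluded from fractions
and tests.

The inter- vs intra-only comparison uses a two-sample KS test on
bp-weighted ECDFs. Effective sample sizes for the p-value are segment
counts, not bp: bp-level counts would be astronomically anti-conservative
because neighbouring nucleotides are perfectly dependent. With equal
weights and small samples the exact two-sample distribution is used;
otherwise the asymptotic Kolmogorov distribution.

Gene association for enrichment: a gene is hit when a changed segment
overlaps its body or promoter window (TSS ± 3 kb default). Branch groups
follow the dot-plot scheme: "Inter (all)" pools patterns whose changes
are confined to inter-type branches; each inter-type branch separately
takes patterns whose only change is on that branch; each cell type's
intra group takes inter-free patterns changing inside that type's clade.
Enrichment per (group, set) is the hypergeometric upper tail
P(X ≥ k) with the universe equal to all genes in the supplied
annotation; Benjamini–Hochberg step-up control is applied within each
group (one family per cluster), significance at adjusted p < 0.05. Gene
sets are harmonized to the universe (out-of-universe ids dropped with a
warning) and size-filtered to 5–500 by default.

## Mark integration

Per internal node and gene, reconstructed ON tracks of each modification
are intersected with the gene body and a 5′ upstream window (5 kb
default; the window size is a configuration knob, not an inference), and
rows that are zero at every node are omitted. On top of the raw bp
table, ACTIVE is called when promoter-region H3K4me3 and H3K27ac both
reach a threshold t, BIVALENT when H3K4me3 and H3K27me3 do; t defaults
to 200 bp (~one nucleosome footprint). The flags are a convenience layer;
the bp table is always emitted.

## Synthetic data generator

The generator emulates the structure the reconstruction assumes:
non-overlapping "modifiable regions" per modification (uniform 500–2,000
bp) evolving independently along the fixed tree as binary states — ON at
the root with p0 = 0.3, gains only from OFF parents and losses only from
ON parents, with per-edge rates 0.05 on inter-type and 0.01 on
intra-type edges — plus whole-region leaf flips at rate 0.01 standing in
for tissue/individual variation. The reference configuration is 3
chromosomes × 1 Mb, 8 cell types × 3 samples, 6 modifications, 300
regions per modification, 150 genes (one per evenly sized slot, strand
Bernoulli(0.5), 2 kb bodies), half the regions anchored at gene
promoters, and gene sets partitioning the genes. Planted enrichment
multiplies the gain rate on one named branch for regions overlapping a
chosen set's promoters. Everything is deterministic given the seed.

What the generator does *not* emulate: peak-caller artifacts, signal
strength, fractional peak overlap between samples, linked regions,
copy-number effects, and per-nucleotide (sub-region) changes. Passing
tests therefore demonstrate correctness of the reconstruction machinery
under the model's own assumptions, not robustness to real-data noise
sources outside that model.

Recovery is scored over the modifiable-region space: internal-node state
accuracy is matching bp / total bp across internal nodes, and events are
(branch, region, direction) triples, a reconstructed change counting when
same-direction changed segments cover >50% of the region (root-branch
events matched direction-free, see above). Under the reference rates the
expected number of true events per region is ~0.9, so a substantial
minority of regions carry multiple events whose minimal reconstruction
legitimately differs from the true history; seed-dependent event recall
sits around 0.83–0.86 with node-state accuracy ~0.99.

The planted-enrichment check uses a configuration sized by a power
calculation rather than the reference one: a single 1 Mb chromosome, two
samples per type, one modification, 100 genes each carrying a cluster of
five promoter-proximal regions (flanking/bimodal promoter peaks), and
four sets of 25 genes. With the 10× gain multiplier this gives each
planted gene a ~0.6 chance of entering the target branch group, enough
for the set to be significant in ≥90% of replicates while the
no-planting false-positive rate stays well under the nominal level.

## Numerical and engineering choices

Newick I/O goes through dendropy at the boundary; BH adjustment through
statsmodels; hypergeometric, Fisher and KS distributions through scipy.
Interval algebra (merge, partition, overlap) is implemented directly on
sorted integer arrays with searchsorted — the per-nucleotide partition is
the package's core encoding step and stays transparent and testable.
Problem sizes in the test suite and acceptance script (3 Mb reference
genome, 50 kb per-nucleotide equivalence genome, 10 search seeds, 50
enrichment replicates) were chosen so the full suite completes in well
under a minute while keeping every stochastic bound comfortably
estimable.

## Known limitations

- Genome-scale inputs (3 Gbp, 100+ samples) are supported by the
  streaming partition contract but have not been exercised here.
- Changes on the root branch have no identifiable direction; tables
  report them under the OFF-root convention.
- The constrained search is a local optimizer; with weak signal it can
  return a local optimum (the strong-signal recovery guarantee is the
  tested property).
- Enrichment uses the supplied annotation as the universe; no ID mapping
  or live database access is provided.
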