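# Methods

## The analysis in brief

Chemosensory receptor families (OR, V1R, V2R, TAAR) expand by gene
duplication, predominantly tandem duplication, which leaves a genomic
signature: paralogs that are close on the tree tend to be close on the
chromosome. The pipeline quantifies that signature in four steps — screen a
candidate repertoire from homology evidence, partition it into
well-supported clades on a gene tree, compare phylogenetic with genomic
distance over all gene pairs, and check organ-specific expression — and the
simulator provides ground-truthed synthetic inputs for all of them.

## Screening model

A candidate must clear three independent evidence gates:

* **Forward homology.** Per-hit thresholds: E-value strictly below 1e-3
  (gene-model/BLASTP search) or 1e-10 (genome/TBLASTN search), and aligned
  length of at least 250 aa. A sequence passes if *any* of its HSPs passes;
  HSP aggregation is deliberately not attempted because a single strong HSP
  is already adequate evidence at these lengths, and summing envelopes
  would require positional bookkeeping the hit tables do not always carry.
* **Reciprocal confirmation.** The best reverse hit (minimum E-value, ties
  broken by maximum bitscore, then lexicographic subject id — a total
  order, so results are permutation-invariant) must belong to a curated set
  of known family members. This is the classic reciprocal-best-hit guard
  against picking up the wrong GPCR subfamily: a candidate whose closest
  relative in a well-annotated proteome is, say, a serotonin receptor is
  discarded no matter how strong its forward hit was.
* **Domain structure.** ORs, V1Rs and TAARs are class-A GPCRs: any
  seven-transmembrane domain annotation suffices. V2Rs are class-C
  receptors with a large N-terminal domain and frequently fragmented gene
  models, so the criterion is cumulative: the union of TM7_3 envelopes must
  cover ≥ 200 aa. The union (not the sum) is used so overlapping envelopes
  are not double-counted.

Split TBLASTN loci are merged transitively when on the same scaffold and
strand with nearest-end gaps strictly below 100 kb, then extended by 900 bp
of flank (clipped at scaffold bounds when lengths are known, otherwise only
at zero) — these loci are emission targets for an external gene predictor,
not gene models themselves.

Gene-model and genome-predicted candidates are reconciled by interval
overlap (≥ 1 bp, same strand); when a model entry has no usable
coordinates, by global-alignment peptide identity ≥ 99% over the shorter
sequence (edlib). Coordinates are the default because they are
assembly-anchored and cheap; identity is the fallback, not the rule. Output
size always equals |model set| + |genome-only loci|.

Internally all intervals are 0-based half-open; TSV output is 1-based
inclusive and BED output 0-based half-open, following each format's
convention.

## Tree operations

Supports are bootstrap percentages on the 0–100 scale. Trees whose supports
all lie in [0, 1] are *rejected* rather than silently rescaled — an
auto-detected rescale would misread a tree that genuinely has uniformly low
supports — unless the caller declares fractional supports explicitly.

**Rooting** requires an explicit outgroup that is monophyletic in the
unrooted topology (the error names the intruding leaves); there is no
midpoint fallback, because midpoint rooting on a tree with rate
heterogeneity across receptor clades can silently split a true clade.
Supports are pinned to edges during rerooting so each support stays with
the bipartition it describes.

**Cophenetic distances** are computed as depth(i) + depth(j) −
2·depth(mrca) via a single postorder pass. The test suite checks this
against two independent routes: brute-force ancestor-chain path enumeration
and dendropy's phylogenetic distance matrix.

**Clade extraction** operationalises "the largest defensible clades": a
node qualifies if its leaves are all focal, number ≥ `min_size` (default
5), and its support is ≥ `min_support` (default 85); the *maximal*
qualifying nodes — no qualifying ancestor — are selected by a preorder
scan that stops descending at the first qualifying node. Clades are
labelled `Clade1..K` by decreasing size, ties broken by the
alphabetically first leaf, which makes labels reproducible across runs
(display order in published figures is not). Focal genes outside every
selected clade are `Else`. A warning (not an error) is raised when fewer
than three clades emerge, since a two-block partition rarely separates
genomic clusters informatively. Non-focal leaves disqualify a node: the
partition is of the focal repertoire alone.

**Reference classification** assigns each focal gene to the group (typical
V2R, CaSR, V2R-like, …) whose defining clade — the smallest clade
containing all of that group's reference leaves — is the smallest one
containing the gene; genes inside no defining clade are `unclassified`.
Smallest-clade tie-breaking makes nested panels (CaSR inside the wider
class-C clade) resolve to the most specific group.

## Genomic distribution

Genomic distance between two genes is the absolute difference of their
interval midpoints — insensitive to gene-length asymmetry, and exactly zero
only for identical midpoints; genes on different scaffolds have undefined
distance. The pair table always contains exactly C(n,2) records and raises
if not: published pair counts in this literature occasionally fall short of
C(n,2) without explanation, and this implementation surfaces such gaps
rather than reproducing them.

The proximity summary counts, per clade class, pairs with defined genomic
distance strictly below the threshold (default 10 Mbp). Interscaffold pairs
can never be "near" but remain in the denominators; pairs involving an
`Else` gene — including Else–Else pairs — are interclade. The summary is
monotone non-decreasing in the threshold and converges, as the threshold
grows, to each class's intrascaffold share.

Scaffold occupancy sorts scaffolds by decreasing length and reports the
fraction of genes on the densest scaffold; scaffolds below 0.1 Mbp are
flagged for display filtering but never dropped from counts, and the
filter does not touch pair statistics.

## Microsynteny

Liftover matches between assembly versions are accepted at E < 1e-100 and
identity > 99% (both strict); multiple accepted targets for one source keep
only the best (E-value, then identity) and set an ambiguity flag. Regions
are eight flanking genes per side by default. Order conservation is defined
as strict monotonicity (either direction) of the partner positions, so an
inversion of the whole block still counts as conserved — the biologically
conservative reading, since a block inversion preserves linkage. The
landmark check reports, for each landmark (e.g. Plch1, Mme), the family
genes sharing its scaffold and whether the nearest lies beyond 50 Mbp
("no or substantially distant").

## Expression

One TPM library per organ, nine organs in the reference design. The display
transform is log10(TPM + 0.001); the pseudocount maps TPM = 0 to −3.
"Expressed in focal" means focal TPM strictly above 1; "highest in focal"
means the focal organ strictly exceeds every other organ — a tie is not
highest, the conservative call (a gene equally expressed in olfactory organ
and brain is not evidence of olfactory specificity). The two calls are
independent: a gene can be highest in the focal organ at sub-threshold
TPM, so `n_highest ≤ n_expressed` is *not* an invariant.

## The simulator: what it emulates and what it does not

Defaults (`SimConfig`): 3 founders on distinct scaffolds, 45 duplication
events (48 genes — a mid-sized repertoire with three major clades),
p_tandem = 0.85, tandem offsets 5–50 kb, 10 scaffolds of 100 Mbp, 20
decoys, exponential branch lengths with mean 0.1 subs/site, supports 90–100
on founder-lineage nodes (≥ 5 leaves) and 20–60 elsewhere, focal-organ TPM
~ LogNormal(μ=3, σ=1) (~20 TPM median) vs. LogNormal(μ=−2, σ=1) (~0.14
TPM) in the other eight organs. These emulate a strongly tandem-expanded
family with clean bootstrap separation of lineages and olfactory-biased
expression.

Mechanics: each event duplicates a uniformly chosen gene; tandem copies
take the nearest free slot within the offset window, scanning downstream
first then upstream (deterministic tie-break), dispersed copies take a
uniform free position on a uniform scaffold; every gene occupies a fixed
1 kb footprint and placements never overlap. Family members receive hit and
domain records that pass every screening gate (E ≤ 1e-50, alignment
≥ 300 aa, TM7_3 coverage ≥ 220 aa); decoys receive records that fail the
forward filter, reverse hits whose best subject is an unrelated GPCR, and
absent or family-rule-failing domains. All randomness flows through one
`numpy` Generator keyed by `seed`; the same seed gives byte-identical
output files.

What it does **not** model, and therefore what green tests do not show
about real data: no sequence evolution (supports are assigned from truth,
not bootstrapped, so tree-inference error is out of scope by design — the
pipeline consumes trees, it does not infer them); no gene loss,
pseudogenisation, assembly fragmentation or mis-scaffolding; E-values are
pass/fail placements, not score distributions, so threshold *calibration*
against real search statistics is untested; expression has no biological
replicates and no between-organ correlation structure. The simulator
demonstrates that the pipeline's logic is correct given honest inputs, not
that the thresholds are optimal for any particular genome.

## Numerical and degenerate-input choices

* E-value and identity thresholds are strict (<, >); length and coverage
  floors are inclusive (≥) — matching the conventions the thresholds were
  stated with.
* An empty pair list, an empty synteny region, an unknown organ or family
  label, a non-monophyletic outgroup, duplicate gene ids — all raise
  immediately with the offending names; an empty *screened candidate set*
  is a legitimate biological outcome and produces a zero-count report with
  a warning, exit status 0.
* Single-gene inputs yield C(1,2) = 0 pairs and no proximity block.
* The pipeline report is deterministic given inputs (JSON with sorted
  keys, no timestamps); re-runs are byte-identical.

## Known limitations

* Reconciliation matches greedily in input order; with overlapping gene
  models on the same strand the pairing (not the counts' invariant) can
  depend on order. Real gene models rarely overlap on one strand.
* Clade extraction assumes the tree is already rooted sensibly; rooting
  inside a true clade splits it, and no automatic detection is attempted.
* `measure_truth` and the inference-side proximity summary share the pair
  table code path by design (the contract is identical); independence is
  provided by the true-vs-inferred *clade labels*, not by a second distance
  implementation.
* The acceptance-style recomputation of a published pair-fraction table
  runs only when the corresponding supplementary files are supplied
  locally; they are not bundled.
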