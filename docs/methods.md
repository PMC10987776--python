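# Methods

## The similarity model

The score of a gene pair is the product S(g₁,g₂) = C(k) · D(k) · S(p₁,p₂),
where k is the intersection of the two genes' *scoring neighborhoods*.
Three modelling choices deserve spelling out, because the bare formula
leaves them open:

**Neighborhood scope.** A gene's scoring neighborhood is its 1-hop
neighbor set unioned with the 1-hop neighbors of every protein linked to
it by `corresponding_to`. The union matters: in this schema the pathway,
localization, domain and family annotations hang off the *protein* node,
so a strict 1-hop gene neighborhood would blind the score to most of the
annotation signal. `ScoringConfig(include_protein_hop=False)` restores
the strict reading. Neighborhoods are undirected — an entity reached by
an incoming edge is a neighbor — and all counts are over entities, so
parallel relations to the same neighbor count once.

**Trait exclusion.** Trait nodes are removed from scoring neighborhoods
by default (`excluded_categories={"trait"}`). Scoring against the very
trait being predicted would leak the label into the evidence; a known
gene's trait edge would otherwise inflate the score of exactly the pairs
the threshold is calibrated on. This is also why the shipped worked
example counts 12 coincident entities while a raw neighborhood
intersection on the same graph would count one more (the shared trait).
The exclusion set is configurable.

**Unscorable is not zero.** A pair whose proteins the similarity
provider does not know raises a distinct error and is skipped by the
batch drivers. Mapping it to S = 0 would silently suppress predictions
for genes that merely lack sequence data. When a gene maps to several
proteins the pair with the maximal provider score is used
(`protein_pair_policy="max"`); the alternative `"first"` is deterministic
by protein id.

## Protein similarity

The default provider aligns the two sequences globally (Biopython
`PairwiseAligner`) under BLOSUM62 with affine gap penalties (open 10,
extend 0.5, a gap of length L costing open + extend·(L−1)) and reports
percent identity over the full alignment length, gap columns included —
a 0–100 scale. When several alignments attain the optimal score the
aligner's first traceback is taken, which is deterministic for fixed
parameters; the test suite checks the optimal *score* against an
independent Gotoh dynamic program and checks that the reported identity
is attained by some optimal-score alignment, since different optimal
tracebacks can differ in identity. The denominator can be switched to
the shorter sequence length.

Because published similarity values (e.g. the 79.191 of the worked rice
pair) come from unspecified tooling, a table provider reads precomputed
scores from TSV keyed by unordered protein pair, letting external values
be injected verbatim. Both providers are exactly symmetric.

## Threshold calibration and evaluation

Labeled gene–gene pairs (positive = the genes are documented to regulate
a common trait) are split by year: pairs at or before the cutoff
(default 2017) train, later pairs validate. Candidate thresholds are the
sorted distinct observed scores — F1 is piecewise constant between
observed scores, so this grid is exact and a denser one cannot change
the result. Ties in F1 resolve to the smallest threshold, maximizing
recall at equal F1. Classification is `score >= threshold`, with the
boundary case explicitly positive. Precision, recall or F1 with a zero
denominator are reported as 0 and flagged in
`EvaluationMetrics.undefined` rather than raising, so degenerate
validation slices stay visible. F1 is always computed from unrounded
counts.

How negative pairs are constructed is a modelling choice the data do not
dictate; the package accepts explicit labels and provides a seeded
uniform sampler over same-population gene pairs sharing no trait
(`sample_negative_pairs`). The pipeline samples as many negatives as
there are positives.

## Prediction, mining and ranking

Per candidate gene and trait, the prediction score is the *maximum* S
over the trait's known genes — one sufficiently similar known gene
suffices, and no aggregation over several supporters is attempted. A
known gene documented for several traits supports each of them; a gene
never supports its own predictions. Genes with ≥ 2 passed traits are
polyphenotype candidates, tabulated by their full trait combination
(each gene in exactly one row, so counts always sum to the cohort size).

For a target trait set of size n, the ranked population is the genes
predicted for *all* n traits. Per-trait ranks descend from the highest
score; Ssum is their arithmetic mean, kept at full precision internally
and rounded to one decimal only for display. Two tie policies exist
because published rank tables are internally inconsistent about ties:
`dense` (default) lets equal values share a rank — so a top-10 cut can
legitimately return more than 10 genes — and `ordinal` breaks ties by
gene id. The choice is recorded in the output.

## DEG overlap validation

DEG tables are consumed as given (no differential-expression calling):
genes with |log FC| ≥ 1 are retained, the threshold inclusive and
configurable, with the fold change conventionally log₂. Each
polyphenotype gene is assigned to exactly one Venn region — the exact
subset of DEG sets containing it — so region counts partition the
cohort; the verified fraction is exact and rounded to whole percent only
for display. No cross-species or cross-nomenclature id mapping is
attempted: fuzzy matching would fabricate overlaps.

## The synthetic study generator

Real graphs of this kind are assembled from curated databases and
literature mining and cannot be shipped; the generator builds small
studies whose ground truth is known exactly. It emulates precisely the
structure the score exploits: each trait owns a signature of
`shared_annotations_signal` annotation entities cycled across seven
categories (so both C and D carry signal, mirroring the worked example's
D = 4); known and planted genes attach to the full signature of their
traits, decoys to at most `shared_annotations_noise` entities from a
single category plus private background annotations. Protein
similarities are ~N(80, 3) for trait-sharing pairs and ~N(15, 3)
otherwise, clipped to [0, 100], emitted as a table by default (the same
code path as injected published scores) or as mutated 60-residue
sequences to exercise the aligner. Association years are laid out so an
8:2 time slice at 2017 exists by construction. The defaults — 3 traits ×
4 known genes, 6 planted unknowns, 12 decoys — keep every bundled file a
few kilobytes while leaving a wide score margin between planted and
decoy pairs.

What passing these fixtures shows: the scorer, sweep, predictor, miner,
ranker and overlap accounting are each correct against independent
oracles, and the full pipeline recovers planted links with precision =
recall = 1 when signal dominates noise, degrading as the gap closes.
What it does not show: performance on real graphs, whose degree
distributions are heavy-tailed, whose annotations are incomplete and
correlated, and whose literature labels are biased toward well-studied
genes. Dataset-scale published figures (graph size, split sizes, the
502.36 threshold, the 0.89/0.91/0.96/0.94 validation metrics, the
4,447-gene census) depend on those source data and are therefore not
reproduced here.

## Numerical and degenerate-input conventions

Duplicate triples collapse on load; self-loops are dropped with a
warning (no relation in the schema is meaningfully reflexive). Entity
ids are case-sensitive and taken verbatim — the source nomenclatures
(LOC_/AT/Zm/TraesCS) are never normalized or mapped. Schema validation
accepts a relation's legal category pair in either orientation, since
adjacency is undirected throughout. Species is an annotation only; the
scorer is deliberately cross-species, homologous-protein edges being
what stitches the species subgraphs together. Empty known sets, empty
validation slices, genes missing from the graph, and unscorable pairs
all produce flagged skips or typed errors rather than silent zeros. All
randomness (negative sampling, fixture generation) flows through seeded
numpy generators; a fixed seed reproduces every file byte-for-byte.

## Known limitations

* The score is a closed-form product, not a learned link predictor: no
  embeddings, paths longer than the protein hop, or edge-type weights.
* C and D are raw counts, unnormalized by node degree, so hub
  annotations (large GO terms) inflate scores on real data.
* Per-trait aggregation is max; corroboration by several known genes
  earns no bonus.
* The threshold is a single global cut; per-trait calibration would
  need per-trait labeled pairs the literature rarely provides.
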