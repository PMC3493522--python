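# Methods

## The classification model

`taxlca` places a query read on a rooted taxonomy of uniquely named, ranked
taxa using only its alignment hits against annotated reference sequences.
Classification of one query is a composition of three total functions:

**Hit selection.** Let *b*\* be the best hit's bit-score. If
*b*\* < *s*<sub>min</sub> the query is reported `unclassified_low_score` and
never reaches the similarity filter. Otherwise the assignment set is every
hit with bit-score ≥ (1 − *x*/100) · *b*\*. Both comparisons are inclusive,
so the printed defaults are themselves admissible values. Multiple HSPs for
one (query, subject) pair collapse to the highest-scoring HSP before
selection — the LCA operates per reference sequence, and a duplicated subject
would double-count its taxon.

**LCA.** The assignment set maps, via the reference database's
accession→taxon index, to a set of taxonomy nodes; the pre-filter placement
is their lowest common ancestor. A single-reference assignment set places the
query on that reference's taxon (a genus in practice — references are mapped
to taxa, never to individual sequences). LCA is computed by root-ward path
intersection; it is commutative, associative over set union and idempotent,
and these properties are asserted against a brute-force oracle in the tests.

**Minimum similarity filter.** Each canonical rank carries a minimum percent
identity to the best reference: species 99, genus 97, family 95, order 90,
class 85, phylum 80; every rank rootward of phylum has threshold 0. A node's
*effective* threshold is that of its nearest ranked ancestor-or-self, so
unranked intermediate clades are transparent. The placement is demoted parent
by parent until its effective threshold is ≤ the best-hit identity
(inclusive), and a demoted query is flagged `unknown_demoted`: it is reported
as an unknown member of the ancestor, which is the intended reading for reads
from undescribed taxa. Because thresholds decrease monotonically toward the
root, the first passing ancestor is the deepest passing one, and lowering
identity can never deepen an assignment.

The *identity used by the filter is the best hit's identity*, with best-hit
ties broken by higher identity, then lexicographic accession — not the
maximum identity inside the assignment set. This keeps the filter a function
of the single best reference alignment.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `lca_range_percent` (*x*) | 2.0 | % of best bit-score | width of the hit-selection window |
| `min_bitscore` (*s*<sub>min</sub>) | 155 | bit-score | gate below which a query is unclassified |
| `rank_thresholds` | 99/97/95/90/85/80 | % identity | species…phylum similarity requirements |
| `max_hits` | 100 | count | hits retained per query |

Decreasing *x* sharpens resolution at the cost of precision (fewer hits vote
in the LCA); 1% is reasonable when most reads match well-characterized
references or reads are long. `min_bitscore` matters mainly for short or
partial alignments; raising it (e.g. to 300) is advisable for long-read
amplicons. The rank thresholds reflect typical minimum SSU rRNA similarities
between nearest neighbors within a taxon and may be re-mapped wholesale for
other markers; the implementation only requires them to increase strictly
with rank depth.

## Rank model

Ranks carry integer depths: root 0, domain 1, kingdom 2, phylum 3, class 4,
order 5, family 6, genus 7, species 8; `norank` (−1) marks unranked nodes.
The "kingdom" slot holds domain/phylum-intermediate levels common in SSU
taxonomies. Rank monotonicity (no node ranked more rootward than its parent,
with norank transparent) is enforced at construction and on file load.

## Serialization

A reference database is a triple: Newick tree-file (labels on every node,
single-quote quoting, no branch lengths emitted; branch lengths tolerated on
input), a tab-separated mapping file (`id  name  rank-depth  parent-id`, one
header line), and a FASTA whose record descriptions carry the assigned taxon
name. Newick parsing is delegated to scikit-bio; the writer is custom because
the output dialect is pinned. Round trips preserve (name, rank, parent, id)
for every node and are asserted byte-stably in the tests: the builder sorts
siblings by name and numbers ids in preorder, so identical inputs give
byte-identical outputs.

## Reference-database construction

Lineage records (accession, root-to-tip path, optional parallel rank labels)
are inserted into a trie under a synthetic root. Ranks are inferred per new
taxon with three rules in order of precedence: the supplied rank label; the
nomenclature suffixes `-ales` → order and `-aceae` → family (the misspelling
`-acaea` is also accepted); otherwise one step deeper than the parent's
effective rank, capped at species. A candidate that is not strictly deeper
than the parent would violate rank monotonicity and falls through to the next
rule. Known limitation: without rank labels, lineages that skip levels are
assigned by depth (e.g. a phylum directly under a domain lands on the kingdom
slot); supplying the optional rank column gives canonical placement.

Manual-changes files contain one operation per line
(`action<TAB>/path/to/taxon<TAB>payload`). Renames rewrite the taxon in every
record whose lineage passes through the target path; deletes drop the taxon's
records entirely (sequences without valid annotation are removed); adds
schedule new internal taxa, which — like any taxon left without sequence
support — are pruned from the output. Each change is re-verified against the
built taxonomy and reported as applied/failed; failures (target not found)
are recorded, not fatal.

## Evaluation harness

Ten-fold cross-validation partitions reference sequences into folds differing
in size by at most one (seeded shuffle, round-robin deal). An optional
stratified mode deals each genus's sequences to consecutive folds, guaranteeing
that any taxon with ≥ 2 sequences is split across folds — the regime in which
a noise-free database is perfectly recoverable. Leave-taxon-out removes a
whole genus/family/phylum subtree (exhaustively, or a seeded sample of *n*
taxa) and prunes unsupported nodes from the retained taxonomy.

Each held-out sequence, optionally cropped to a uniform-random 100 or 450 bp
window (too-short sequences are skipped and counted), is aligned to the
retained references and classified. At each rank, exactly one of TP/TN/FP/FN
is scored: an assignment at the rank is TP if it names the truth's taxon and
FP otherwise; no assignment at the rank is TN when the truth has no taxon
there *or* that taxon is absent from the retained reference, else FN.
Sequences whose truth lacks annotation at a rank therefore contribute TNs
(they are correctly unclassified there) rather than being dropped; precision
and recall are unaffected because such sequences can produce no TP or FN at
that rank unless misassigned. Accuracy = (TP+TN)/total, precision =
TP/(TP+FP), recall = TP/(TP+FN), with zero-denominator ratios reported as
absent rather than coerced.

For the taxon-removal design, a held-out read of the removed taxon is counted
as handled correctly when it is a TN at the removed rank *and* its
assignment, if any, lies on the true lineage — novelty should fall through to
an ancestor, never into a sibling. This composite is isolated in
`removed_taxon_accuracy`.

Precision–recall curves over the LCA range exploit the structure of hit
selection: as *x* grows, hits enter in descending score order, at breakpoints
*x*<sub>i</sub> = 100 (1 − *b*<sub>i</sub>/*b*\*), and the pre-filter LCA
coarsens stepwise. Each query is profiled once and thresholded per grid
value; equivalence with naive per-grid reclassification is asserted on
fixtures. The default aligner inside the harness is the simulated-hit oracle,
so evaluation needs no external binary; any callable with the same signature
(e.g. a shell-out to a real aligner) can be substituted.

## Synthetic fixtures

The generator emulates, at desk scale, the structure a curated SSU reference
database gives the classifier. A `FixtureSpec` fixes fan-outs and percent
divergences for six levels (domain…genus), sequences per genus, a
per-sequence divergence, sequence length and a mandatory seed. A random root
ancestor sequence is mutated along each edge by `round(d·L/100)`
substitutions at distinct positions (always to a different base), and each
genus receives its references as further mutants of the genus ancestor. The
default — fan-outs (2,2,1,1,2,2), divergences (15,10,5,3,2,1)%, 3 sequences
per genus at 1% each, length 500 — yields 16 genera / 48 references: small
enough for seconds-scale tests, deep enough that every rank threshold is
exercised. A second, deliberately well-separated configuration (divergences
20/12/8/6/4/3%, identical sequences within each genus) is used where exact
recovery is the property under test.

The hit simulator reports exact ungapped Hamming identity and the linear
score 2·matches − 3·mismatches floored at 0, emitting hits in descending
score order. It is an oracle for classifier logic — every selection threshold
is hand-computable — not an aligner emulator: there are no gaps, no partial
alignments, no E-value model, no compositional bias. Consequently, passing
evaluation on fixtures validates the *logic* of selection/LCA/demotion and
the bookkeeping of the harness; it does not predict accuracy on real reads,
where alignment artifacts (notably partial alignments of truly novel phyla)
dominate the error budget.

Amplicon query sets draw genera with a power-law rank-abundance skew
(exponent 1.5), attach lognormal integer read weights via the trailing `_N`
naming convention, and optionally mutate each query by a fixed noise
percentage. All randomness flows through explicit seeds; there is no hidden
global RNG state anywhere in the package, and seeded pipelines are
byte-reproducible.

## Numerical and edge-case choices

- Bit-score gate and rank thresholds are inclusive (≥); document-level
  defaults are therefore themselves admissible.
- `x = 0` keeps exactly the hits tied with the best bit-score.
- Hit ordering, and hence every downstream decision, is a pure function of
  hit content (score, then identity, then accession), so classification is
  invariant under permutation of input rows.
- Chao1 uses the classic form S + F1²/(2F2) when doubletons exist and the
  bias-corrected S + F1(F1−1)/2 when F2 = 0; singletons/doubletons are counted
  over unique sequences of weight exactly 1 and 2, matching dereplicated
  amplicon semantics, and are computed on post-demotion assignments (the
  taxon the user sees).
- Composition tables carry an explicit `Unclassified` row per rank (weight
  assigned rootward of that rank), making every table sum to the total input
  weight; abundances print as integers when all weights are integral, else
  with two decimals.
- `weight=N` beats a trailing `_N` when both appear; `_N` is recognized only
  as a terminal all-digit suffix, since dereplication pipelines produce names
  with internal underscores.
- Duplicate taxon names, duplicate accessions and duplicate query ids are
  rejected outright rather than silently merged.

## Problem sizes

Tests and the evaluation examples run on the 48-sequence default fixture
(ten-fold CV over it completes in well under a second); the oracle-equivalence
suite uses 1,000 randomized queries. These sizes were chosen to keep the full
suite in the seconds range while covering every rank boundary; all generators
scale by `FixtureSpec` if larger studies are wanted.

## Known limitations

- No gapped-alignment or query-coverage correction: percent identity is taken
  as the aligner reports it (tabular column 3) or as identities/align-length
  (XML).
- The species threshold is implemented and tested, but typical SSU reference
  annotations stop at genus, in which case species rows simply never appear.
- No chimera detection, denoising or abundance rarefaction — upstream tools'
  jobs. No diversity indices beyond Chao1.
- The builder assumes pre-filtered, pre-cropped reference sequences; curation
  quality screens are out of scope.
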