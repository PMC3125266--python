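# Methods

This note records the models behind each stage, the conventions and defaults
the package commits to, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Coordinates and distances

All genomic intervals are 1-based and fully closed, in every container and on
disk (GFF3, BLAST tabular and the package's own TSVs share the convention).
The distance between two intervals is the number of bases strictly between
them: any overlap gives 0, and two intervals that touch with no intervening
base also give 0. Touching intervals still classify as flanking (A/B) — only
a genuine overlap triggers the overlap classes C–F. On a 100-bp toy
chromosome with a gene at [41, 60], unit-length contigs therefore report
distance 0 from 22 placements (20 overlapping, 2 touching), and the null
simulator is tested against exactly that enumeration.

"Upstream" and "downstream" are genomic-coordinate notions (position 345 is
upstream of position 350 regardless of strand). Feature ordinals are
transcript-order and strand-aware: exon 1 of a minus-strand gene is its
right-most exon in genomic coordinates. Both conventions apply everywhere,
including the C/D/F feature labels.

## Tissue specificity

τ = Σᵢ (1 − TPMᵢ/TPM_max)/(N − 1) over N tissues, computed on TPM values
floored at 2. The floor (default 2, in TPM units) makes "expression close to
zero" precise: it prevents a contig with a handful of reads in one tissue and
zero elsewhere from scoring τ = 1 on sampling noise alone. One consequence is
the exact closed form τ = 1 − 2/TPM_max for genuinely single-tissue contigs,
which the tests assert to machine precision. A contig with no reads anywhere
has no τ (reported missing, never 0): flooring an all-zero row would
masquerade as perfectly uniform expression.

Breadth classes are exhaustive: *ubiquitous* (every tissue ≥ 1 read),
*tissue-specific* (all reads in one tissue, ≥ 4 of them — the four-read rule
guards against singleton reads), *absent* (no reads), *intermediate*
(everything else). The named extremes are the scientifically interesting
ones; the two extra labels exist so the per-tissue summary table partitions
the contig set, an invariant the tests check.

## Positional annotation and the random-placement null

Nearest-gene search measures to the gene span (the start of the 5' UTR to the
end of the 3' UTR). Ties are broken deterministically by lower gene start,
then gene id. Chromosomes without annotated genes report a missing distance
rather than 0 or infinity.

The null re-places contigs at random: per replicate, a length is drawn
uniformly from the supplied contig-length list, a chromosome with probability
proportional to its length *among those the contig fits on*, and a start
uniform over the fitting range — the contig always lies wholly on one
chromosome. The default replicate count is 10⁶; tests and examples scale this
down (5 × 10³ – 5 × 10⁴) as their chosen problem sizes, since the toy-genome
enumeration check bounds the estimator's correctness independently of n.
Observed-vs-null comparisons use the two-sample Kolmogorov–Smirnov test with
the asymptotic p-value (scipy); when the observed sample contains only
flanking contigs, the null sample is likewise conditioned on distance > 0.

Binned density uses left-closed right-open bins anchored at coordinate 1
(default width 500 kb), counting alignment start positions, optionally
weighted by read depth.

## SNP filter cascade

The cascade order and constants: (1) SNP quality > 30 and minimum
neighbouring-base quality > 20, with "six neighbouring bases" read as three
per side and stored as a precomputed minimum so the filter is table-local;
(2) indels removed; (3) depth < 8 removed; (4) minor/depth < 25% removed in
the closed depth band [8, 20] (strict inequality); (5) at depth > 20,
minor count < 5 removed at high stringency, < 3 at modest; (6) proximity.

Step 6 is *simultaneous*, not cascading: the polymorphism set against which
proximity is measured is the full set of survivors of steps 1–5 **plus**
indels that passed the quality screen, and every member within the tier
distance (50 bp high / 40 bp modest, positional offset, strict `<`) of
another member — or that close to a contig end — is removed in one pass.
This is why a SNP kept at high stringency can vanish from the modest file:
the modest tier admits more neighbours, and a new neighbour within 40 bp
re-excludes a previously clean site. Whether quality-passing indels should
participate in the proximity set is not derivable from first principles;
they do here, on the argument that a real indel signal is still a
polymorphism crowding the site.

Distance-to-end uses the same offset convention: a SNP at position p fails
when p − 1 < d (start side) or L − p < d (end side) for contig length L.

Remap confirmation intersects kept SNPs with a second candidate table keyed
by (contig, position, ref, alt) — identical alleles required, not just the
position. Coding effects use the standard genetic code via Biopython;
ambiguous bases are an error, not a guess.

SNP strings: two or more SNPs with fewer than 8 intervening bases between
consecutive members (offset ≤ 8) form a string; maximal runs partition the
positions. A 5-SNP string therefore spans at most 4 × 8 + 1 = 33 bases.
Strings of ≥ 6 members flag the contig as a splice-variant candidate.

## Microsatellite scan

For each seed position and unit length k ∈ {2..5}, extension compares each
subsequent base with the corresponding base of the *seed unit* (+1 match,
−6 mismatch, N never matches); the seed unit itself scores 0. The scan stops
when the running score drops below zero and trims back to the maximum-score
prefix; loci require score ≥ 6 and ≥ 5 complete units. Comparing against the
seed unit (rather than the base k earlier) makes an isolated substitution
cost exactly one mismatch — a mid-tract error in (AAG)₆ scores 14 − 6 = 8 —
and is the reading consistent with "adjust scores for the first unit cell".

Mononucleotide and self-periodic seed units (AA, ATAT) are never extended;
every locus is reported once with the lexicographically smallest rotation of
its unit. Overlapping candidates are deduplicated greedily by score, then
span, then smaller unit length. The scanner handles substitutions only; the
original repeat finders also recurse over indels, so diverged repeat tracts
interrupted by insertions are reported as separate loci here. On perfect
repeats bounded by non-matching background the scan provably equals a
regular-expression oracle, which the tests assert interval-for-interval;
inside random background a locus may extend a few bases past the perfect
tract when flank bases happen to match the unit.

Flank extraction takes up to 100 bp per side (≤ 200 bp total), truncated at
contig ends, flagging records with under 10 bp on either side.

## GO pedigrees

The OBO 1.2 parser (obonet + networkx underneath) keeps is_a and part_of
edges separate, merges alt_ids into primary ids, retains obsolete terms as
addressable but untraversable, errors on a term without a namespace, and
rejects cyclic files at parse time rather than defending every traversal.
A pedigree enumerates all simple paths from a term to a root (a term with no
is_a parents — the three namespace apexes) under either is_a-only or
is_a+part_of semantics. Enumeration is capped (default 10,000 paths) with an
explicit truncation flag, since deep DAGs hold combinatorially many paths.
is_a-only roots are always a subset of combined-semantics roots, and always
include the term's own namespace apex — both are asserted as properties.

A GO term is unique to tissue t when it is attached to at least one
tissue-specific(t) contig and to no contig expressed in any other tissue.
Per-term τ aggregates as the maximum over the term's contigs (an aggregation
rule the underlying analysis leaves open; the maximum reports the strongest
specificity evidence available for the term).

## Homology summaries

Best-hit retention keeps, per query, the lowest e-value at or under 10⁻⁵,
ties broken by higher bit score then first occurrence — idempotent by
construction. Identity clustering links two contigs when a *single* HSP
reaches 95% identity across ≥ 95% (or 100%) of the shorter contig, and takes
connected components (single linkage); summing multiple HSPs toward coverage
would be more permissive and is deliberately not done. Reciprocal pairs
classify as single, multiple_overlapping, or multiple_disjoint (every HSP
pair non-overlapping on both sequences); collinearity is reported but not
required for disjointness, because an intron retained in one contig produces
disjoint but non-collinear alignments in one coordinate system.

GC content is the G+C fraction of unambiguous bases only, with the IUPAC
ambiguity fraction reported separately; an all-ambiguous sequence has no GC
value. Contamination triage maps hit genera to taxonomic groups through a
packaged, editable TSV and applies a fixed precedence: any bird hit confirms
the contig; any other vertebrate group suggests a real gene without a bird
homologue; hits spanning ≥ 2 kingdoms are treated as unresolvable spurious
alignments; a single foreign kingdom marks a contamination candidate.
The Welch unequal-variance t statistic (scipy) serves the read-depth and
tissue-count contrasts.

## The synthetic-data generator

The generator emulates the *structure* the analysis assumes, not the
sequencing process. A genome of four chromosomes (1 Mbp total by default)
carries 80 non-overlapping genes whose 5'UTR–exon–intron–3'UTR features tile
their spans exactly; 400 contigs are drawn from a mixture of mRNA (spliced
exon sequence), pre-mRNA (a window inside a single intron — the dominant
observed pattern for unspliced contigs), intergenic-near (within 5 kb of a
gene, matching the distance-table reporting bins) and intergenic-far
(uniform placement avoiding genes). The default mixture
(0.35/0.35/0.20/0.10) reflects a study in which roughly a third of contigs
match known transcripts and most of the remainder lie in or very near genes;
the true mixture of a real assembly is unknown, and these weights are
calibration choices, not estimates. Expression plants 21% single-tissue
contigs (≥ 4 reads) over 8 tissues with gamma-Poisson totals elsewhere;
SNP tables plant cascade-clean true sites (≥ 60 bp apart, ≥ 50 bp from ends)
at 1/kb and rule-violating artifacts at 2/kb, each artifact violating one
named rule while staying isolated enough not to disturb the true sites;
perfect and one-mismatch microsatellites are planted at recorded positions.
A miniature three-namespace GO DAG with one cross-namespace part_of edge and
a 74%-annotated gene→term map completes the inputs.

Every synthetic entity carries a truth label, so recovery tests score the
classifiers exactly. All randomness flows through a single seeded
`numpy.random.Generator`; identical seed and configuration give
byte-identical output files.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: read-level error models and quality scores,
assembly artifacts (chimeras, collapsed paralogues), homopolymer indel noise
typical of pyrosequencing, alternative isoforms in the gene models,
sequence-composition biases (GC is uniform at ~50%), and real ontology-scale
GO topology. Recovery rates on synthetic data are upper bounds: the planted
signals are unambiguous by construction.

## Problem sizes

The shipped tests use the generator defaults (400 contigs, 1 Mbp genome),
10⁴ replicates for the enumeration check, 5 × 10³ per sample for KS power
and calibration (50 seed pairs), and 5 × 10⁴–10⁵ null replicates in the
examples; the full 10⁶-replicate null remains the library default and is a
single function argument away.

## Known limitations

Nearest-gene search in `annotate()` is a per-chromosome linear scan (exact
for any gene layout, including overlapping genes); the vectorised index used
by the null simulator assumes non-overlapping genes, which the generator
guarantees but real annotations may not. The microsatellite scanner's
mismatch-only extension under-reports indel-interrupted repeats. Pair
classification trusts the HSP table it is given; it does not re-align.
Genus triage is only as good as the packaged genus→group map, which is
intentionally small and editable.
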