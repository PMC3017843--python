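# Methods

`ugms` re-implements, as a tested library and CLI, the standard analysis
chain for unigene-derived microsatellite (UGMS) markers: mining simple
sequence repeats (SSRs) in transcript sequences, placing them in their
genic context, screening cross-taxon repeat-length variation in silico,
turning fragment-analysis peak tables into genotype calls and marker
statistics, and summarising panel-level diversity with Nei–Li/UPGMA
bootstrap trees. This note records the models, the defaults and why they
were chosen, and what the synthetic data do and do not show.

## SSR detection and classification

A perfect SSR is a maximal uninterrupted tandem array of a primitive
motif of 1–6 nt. The detector scans each motif length for maximal
periodic stretches (a position matches the symbol one period back);
only whole repeat units count, a trailing partial unit never extends a
run, and `N` never matches a motif position, so ambiguity codes
terminate runs. Non-primitive motifs are folded into their primitive
root ((ATAT)n is reported as (AT)2n), avoiding double counting.

Minimum repeat counts default to mono 9, di 6, tri 4, tetra/penta/hexa 3
whole units. These are chosen so that the shortest reportable di- to
tetranucleotide tract is 12 nt — the lower bound of the "potentially
variable" class II — and so that mononucleotide tracts start at 9 bases,
the lower end of the range such surveys report. All are configurable.

When maximal runs of different motif lengths overlap (a poly-A inside a
longer (AT)n context, say) one call is made per locus: the longest tract
wins, ties go to the shorter motif, then to the leftmost start. Repeat
counts above 100 units are retained internally but capped at 100 in
reports.

Motifs are reported both as read and canonically: the canonical motif is
the lexicographically smallest cyclic rotation of the motif or of its
reverse complement, so AG, GA, TC and CT fall into one class. The map is
idempotent and partitions all primitive motifs of length ≤ 6 (checked
exhaustively in the tests).

Length classes follow the usual convention for transcript SSR surveys:
class I (long, hypervariable) at total tract length ≥ 20 nt, class II at
12–19 nt, shorter tracts labelled `below_class_II`.

Two or more runs separated by at most 100 nt form a compound SSR —
non-interrupting when adjacent (every gap 0), interrupting otherwise.
The interrupting flag keys on spacer presence, not motif change: two
runs of the same motif separated by a spacer are an interrupting
compound. Runs farther apart than 100 nt stay standalone.

Corpus summaries report raw tallies plus derived densities (kb of
sequence per SSR) and percentages. The denominator conventions mirror
how such survey tables are printed: di- to hexanucleotide fractions and
the class I fraction are over the perfect SSR count excluding
mononucleotides; the mononucleotide fraction and all sequence-level
fractions are over the number of sequences; the multi-SSR fraction is
over SSR-bearing sequences; the interrupting split is over compounds.
Because opinions differ on whether compound members are also perfect
SSRs, both counts are carried (`n_perfect_excl_mono` includes members,
`n_perfect_standalone_excl_mono` does not); ratios use the inclusive
count. Zero-denominator ratios are reported as undefined, never as 0.

## Genic context

Gene structure (a CDS interval per transcript, forward strand, length
divisible by 3) is an input; transcripts without a model are labelled
`unannotated` rather than guessed, since structure prediction is out of
scope. An SSR wholly before/inside/after the CDS is 5'UTR/CDS/3'UTR;
boundary-spanning SSRs go to the region holding the larger fraction,
ties to CDS — the choice is arbitrary but deterministic and documented.

For trinucleotide repeats inside the CDS the module reports the reading
phase (`(start − cds_start) mod 3`) and the amino acid encoded by the
first complete codon within the tract, translated with the standard
genetic code. A tract at phase 1 or 2 therefore encodes the in-frame
cyclic rotation of its motif; grouping codon families into amino-acid
classes is left to the caller, since the in-frame codon is the datum.

## In-silico polymorphism

Given repeat-unit counts at homologous loci (locus × taxon; homology is
an input, matched by locus id), a locus is polymorphic for a taxon pair
when the counts differ. Percentages use the loci present in both taxa
of the pair; pairs sharing no locus are undefined. Polymorphism is
defined on unit counts, not fragment length, because the in-silico
comparison is about repeat-length variation at the same motif.

## Fragment genotyping

Peaks are retained iff height ≥ 1500 fluorescence units and quality
≥ 6.0 (both inclusive); sizes are rounded to integer bp, matching the
granularity at which allele sizes are reported. Per primer, distinct
sizes are sorted and a new locus starts at every gap ≥ 100 bp
(single-linkage), loci labelled a, b, c… by ascending size — a primer
may amplify several loci in a polyploid. Missing amplification is
recorded as missing and excluded from frequencies and group calls.

A sample is heterozygous at a locus iff it shows ≥ 2 distinct sizes
(allele dosage is unresolved in polyploids). Allele frequencies count
each distinct allele occurrence per sample as one observation — the
standard convention for polyploid fragment data — with per-sample
presence weighting available as an alternative. PIC = 1 − Σp². A locus
is P (polymorphic) for a sample group iff the group shows more than one
allele there.

Allele-size distributions are classified against the stepwise mutation
model: stepwise iff all sizes at a locus are congruent modulo the
repeat-unit length (equivalently, every pairwise difference is an exact
multiple of the unit — no reference allele is needed), mixed otherwise
(some differences involve flanking insertions/deletions), undetermined
for a single allele.

## Diversity

Genotypes are scored as allele presence/absence over (locus, size)
rows. The Nei–Li coefficient is used in its Dice form
S = 2·n11 / (2·n11 + n10 + n01), the standard reading for band-sharing
data; two empty profiles have undefined similarity (error). Distance is
d = 1 − S.

UPGMA is implemented in-package rather than delegated, because a
reproducible tree needs a pinned tie-break: the closest pair is merged
(ties to the lowest pair of original label indices), inter-cluster
distance is the size-weighted mean of member distances, node height is
d/2. The result is ultrametric; on an ultrametric input the cophenetic
distances reproduce the input exactly. Tests cross-check cophenetic
distances against SciPy's average-linkage clustering as an independent
oracle.

Bootstrap resampling draws whole marker loci with replacement — allele
rows of one locus move together because they are not independent — and
rebuilds the tree per replicate. Support of a clade is the percentage
of replicates containing it; since UPGMA replicate trees are rooted and
ultrametric, clades are counted directly (majority clades of rooted
trees are always mutually compatible, so the > 50% consensus assembles
without a compatibility filter). Defaults: 1000 replicates, 50%
majority rule, supports as integer percentages; minority bipartitions
are not added. The point-estimate tree is emitted in Newick with branch
lengths (height differences) and supports as internal-node labels; the
consensus without branch lengths.

## Synthetic data

`simulate_corpus` builds transcript-like sequences (defaults: 24
sequences of 0.4–1.5 kb, GC 0.5, one gene model each with UTR5/CDS/UTR3
at roughly 20/60/20%) and plants the specified repeats round-robin with
≥ 10 nt of background between blocks. Background is drawn by rejection:
a candidate segment containing any run that meets the detection minima
is redrawn, and the assembled sequence is accepted only when an
independent plain run-scanner (deliberately separate from the mining
module) finds exactly the planted intervals. The truth manifest
therefore lists the complete, exact ground truth, and planted-recovery
tests demand 100% precision and recall.

`simulate_panel` generates peak tables for a grouped panel. Stepwise
loci draw allele sizes as base + k·unit; mixed loci shift one allele by
an offset not divisible by the unit, mirroring a flanking indel.
Group-diagnostic loci carry disjoint alleles per group. One allele
assignment per locus follows a seeded permutation of sample slots so
every allele in a locus's pool is observed somewhere without aligning
choices across groups; heterozygotes (rate 0.3 by default) add a second
allele. Noise peaks always fail the height/quality filter. The shipped
3-group preset makes diagnostic loci the majority of the panel (11 of
18), emulating a species-level study in which nearly all markers
separate the groups and the grouping is definitive; under that design
the three group clades reach bootstrap support ≈ 100.

`simulate_homolog_table` fixes a reference taxon and mutates each other
taxon's unit count per locus with its divergence rate, so observed
reference-vs-taxon polymorphism percentages converge on the planted
rates (±2 points at 10⁴ loci, checked by test).

What the synthetic data do **not** emulate: sequencing error and
assembly chimerism in real unigene builds, imperfect/interrupted
repeats, stutter and pull-up artefacts in electropherograms, size-calling
bias against a ladder, and realistic allele-frequency spectra. Passing
the recovery tests shows the pipeline is correct on its own definitions,
not that those definitions capture every artefact of real data.

## Numerical and degenerate-input choices

Frequencies must sum to 1 within 1e-9; PIC agrees with direct summation
within 1e-12. Ultrametricity is asserted within 1e-9. Zero-denominator
summary ratios are undefined (`None`/NA), never 0. Peak-filter
thresholds are inclusive on both sides. Locus binning depends only on
the multiset of sizes, not row order. All stochastic stages take a
single seed; fixed seed gives byte-identical outputs.

## Problem sizes

The test suite runs the detector-vs-enumeration equivalence on 1000
random 2-kb sequences (a quarter with planted repeats), bootstrap
checks at 100–200 replicates on 6–12-sample panels, and the homolog
convergence check at 10⁴ loci; the whole suite completes in well under
a minute on one CPU. These sizes were chosen as the smallest at which
the properties are non-trivially exercised.

## Known limitations

Absolute counts of a historical corpus cannot be regenerated without
the original sequence build and mining settings; only ratio-level
reproduction is possible, and that is what the acceptance checks do.
Imperfect (mismatch-containing) repeats, reverse-strand gene models and
amino-acid repeat detection are out of scope. The bootstrap consensus
is plain majority rule; compatible minority bipartitions are never
added.
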