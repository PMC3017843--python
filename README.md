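# ugms — unigene-derived microsatellite marker toolkit

Transcript (unigene) collections are a rich source of functionally
relevant microsatellite markers: simple sequence repeats (SSRs) sitting
in expressed genes, whose length variation can be assayed cheaply by
fluorescent fragment analysis. `ugms` is a library and command-line
toolkit for the full marker workflow used in such studies, from repeat
mining to diversity trees. It is aimed at plant/crop geneticists working
with polyploid species (sugarcane being the motivating case), where a
primer may amplify several loci and allele dosage is unresolved.

The pipeline stages:

1. **SSR mining** — maximal perfect repeats of primitive 1–6 nt motifs
   (defaults: ≥9 mono, ≥6 di, ≥4 tri, ≥3 tetra–hexa units), canonical
   motif classes closed under rotation and reverse complement (AG = GA =
   TC = CT), class I (tract ≥ 20 nt) vs class II (12–19 nt), compound
   repeats for runs ≤ 100 nt apart (interrupting iff spaced), and
   corpus summary statistics (densities in kb/SSR, percentages).
2. **Genic context** — CDS / 5'UTR / 3'UTR assignment from gene-model
   inputs, plus the in-frame amino acid encoded by trinucleotide
   repeats in coding regions.
3. **In-silico polymorphism** — cross-taxon repeat-unit-count
   differences at homologous loci, as pairwise percentages.
4. **Fragment genotyping** — peak filtering (height ≥ 1500, quality
   ≥ 6.0), locus binning (new locus at every ≥ 100 bp size gap),
   heterozygote calls, stepwise vs mixed allele-size distributions
   (stepwise iff all sizes congruent modulo the repeat unit), P/M calls
   per sample group and PIC = 1 − Σp².
5. **Diversity** — Nei–Li (Dice) similarity on allele presence/absence,
   S = 2·n11/(2·n11 + n10 + n01), UPGMA with deterministic tie-breaks,
   and bootstrap supports from locus-level resampling with a 50%
   majority-rule consensus, all written as Newick.
6. **Synthetic data** — generators for unigene-like corpora with
   planted repeats, grouped genotyping panels and homolog tables, each
   with exact ground-truth manifests (see `docs/methods.md`).

## Worked example

Simulate a small corpus with planted repeats, mine it, and annotate:

```sh
ugms simulate --preset corpus-small -o sim
ugms mine sim/corpus.fasta -o ssrs.tsv --summary-out summary.txt
ugms annotate ssrs.tsv sim/gene_models.tsv --fasta sim/corpus.fasta -o anno.tsv
```

`ssrs.tsv` begins:

```
seq_id   start  end  motif  canonical_motif  n_repeats  total_len_nt  length_class  role
UG00001  105    138  CT     AG               17         34            class_I       standalone
UG00002  485    570  AT     AT               43         86            class_I       standalone
UG00003  426    455  GCA    AGC              10         30            class_I       standalone
```

i.e. a (CT)17 tract at positions 105–138 of UG00001 — 34 nt, class I,
canonical motif AG — exactly where the truth manifest
(`sim/truth_ssrs.tsv`) planted it. The summary reports the corpus
tallies and derived ratios (`density_kb_per_ssr 1.5` means one SSR per
1.5 kb in this repeat-dense synthetic corpus; `pct_class1 64.7` the
class I fraction of non-mononucleotide SSRs).

Genotype a simulated three-group fragment-analysis panel and build
trees:

```sh
ugms simulate --preset panel-3group -o panel
ugms genotype panel/peaks.tsv panel/markers.tsv --groups panel/groups.tsv -o geno
ugms diversity geno.genotypes.tsv --bootstrap 200 --seed 7 -o div
```

`geno.locus_stats.tsv` begins:

```
primer_id  locus  n_alleles  size_range  distribution_class  n_heterozygous_samples  pic
UG01       a      4          150-156     stepwise            5                       0.7474
UG02       a      3          120-124     stepwise            0                       0.6667
```

UG01 locus *a* shows four alleles whose sizes differ by multiples of
its 2-nt unit (stepwise), five heterozygous samples, and PIC 0.75 —
a highly informative marker. `div.consensus.nwk` holds the majority-rule
consensus with bootstrap percentages as internal node labels; on this
panel the three sample groups form clades with support 100.

All stages are equally usable as a library (`ugms.find_perfect_ssrs`,
`ugms.locus_stats`, `ugms.bootstrap_consensus`, …).

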