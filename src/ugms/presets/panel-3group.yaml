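# Three-group marker panel emulating a species/genera-level study: 12
# samples in 3 groups, 16 primers.  Most markers are group-diagnostic
# (each group carries its own allele, disjoint between groups), as in
# panels where nearly all markers separate species; UG12 carries a
# mixed-distribution locus, UG09 amplifies two loci (>= 100 bp apart)
# like a multi-locus polyploid marker, and 20 sub-threshold noise peaks
# are sprinkled in.
kind: panel
n_groups: 3
samples_per_group: 4
heterozygosity: 0.3
missing_rate: 0.0
n_noise_peaks: 20
seed: 7
loci:
  - {primer_id: UG01, motif_len: 2, base_size: 150, n_alleles: 4}
  - {primer_id: UG02, motif_len: 2, base_size: 120, n_alleles: 1, diagnostic: true}
  - {primer_id: UG03, motif_len: 3, base_size: 200, n_alleles: 1, diagnostic: true}
  - {primer_id: UG04, motif_len: 2, base_size: 240, n_alleles: 1, diagnostic: true}
  - {primer_id: UG05, motif_len: 3, base_size: 180, n_alleles: 4}
  - {primer_id: UG06, motif_len: 4, base_size: 160, n_alleles: 1, diagnostic: true}
  - {primer_id: UG07, motif_len: 2, base_size: 90, n_alleles: 5}
  - {primer_id: UG08, motif_len: 5, base_size: 210, n_alleles: 1, diagnostic: true}
  - {primer_id: UG09, motif_len: 2, base_size: 206, n_alleles: 4}
  - {primer_id: UG09, motif_len: 2, base_size: 481, n_alleles: 3}
  - {primer_id: UG10, motif_len: 6, base_size: 130, n_alleles: 1, diagnostic: true}
  - {primer_id: UG11, motif_len: 3, base_size: 300, n_alleles: 1, diagnostic: true}
  - {primer_id: UG12, motif_len: 3, base_size: 154, n_alleles: 4, mode: mixed, indel_offset: 2}
  - {primer_id: UG13, motif_len: 2, base_size: 110, n_alleles: 1, diagnostic: true}
  - {primer_id: UG14, motif_len: 4, base_size: 175, n_alleles: 1, diagnostic: true}
  - {primer_id: UG15, motif_len: 3, base_size: 260, n_alleles: 1, diagnostic: true}
  - {primer_id: UG16, motif_len: 2, base_size: 330, n_alleles: 1, diagnostic: true}
  - {primer_id: UG17, motif_len: 3, base_size: 140, n_alleles: 1, diagnostic: true}
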