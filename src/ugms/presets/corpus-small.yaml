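# Small unigene-like corpus: 24 transcripts, planted mono- to
# hexanucleotide repeats across UTR5/CDS/UTR3, two compound repeats.
kind: corpus
n_sequences: 24
min_len: 600
max_len: 1500
gc: 0.5
seed: 1
planted:
  - {motif: CT, n_repeats: 17, location: UTR5}
  - {motif: AT, n_repeats: 43, location: CDS}
  - {motif: GCA, n_repeats: 10, location: CDS}
  - {motif: GGC, n_repeats: 7, location: CDS}
  - {motif: TA, n_repeats: 21, location: UTR3}
  - {motif: T, n_repeats: 30, location: UTR3}
  - {motif: AGGA, n_repeats: 9, location: CDS}
  - {motif: TTTTC, n_repeats: 7, location: UTR5}
  - {motif: CCTCGC, n_repeats: 6, location: CDS}
  - {motif: AG, n_repeats: 18, location: CDS}
  - {motif: TC, n_repeats: 8, location: CDS}
  - {motif: ACA, n_repeats: 5, location: UTR5}
  - {motif: GA, n_repeats: 10, location: UTR3}
  - {motif: AAG, n_repeats: 10, location: CDS}
  - {motif: AG, n_repeats: 8, location: CDS, partner_motif: CTT, partner_repeats: 6, gap: 40}
  - {motif: GCC, n_repeats: 6, location: CDS, partner_motif: TGA, partner_repeats: 5, gap: 0}
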