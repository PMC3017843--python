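# Homologous-locus repeat counts for a sugarcane-vs-cereal style
# comparison; rates are the planted per-taxon divergence from the
# reference taxon.
kind: homolog
n_loci: 350
taxa: [sugarcane, rice, wheat, maize, sorghum, barley]
rates: {rice: 0.30, wheat: 0.425, maize: 0.25, sorghum: 0.178, barley: 0.466}
seed: 13
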