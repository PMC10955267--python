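# Karlin-Altschul parameters for the gapped scoring presets.
# Published values: BLOSUM62 with gap open 11 / extend 1, and the
# blastn 2/-3 family with gap open 5 / extend 2 (NCBI BLAST tables).
# The bisulfite presets reuse the nucleotide constants: the asymmetric
# matrices perturb the random-alignment score distribution, but no
# published constants exist for them (documented approximation).
# preset	lambda	K
blosum62	0.267	0.041
nt	0.625	0.410
bs_ct	0.625	0.410
bs_ga	0.625	0.410
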