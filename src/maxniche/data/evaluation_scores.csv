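parameter,before_rarefying,after_rarefying
species_occurrence_points,16353,9234
AUC,0.612,0.776
TSS,0.624,0.788
Kappa,0.513,0.685
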