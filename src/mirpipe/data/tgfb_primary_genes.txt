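# Primary genes of the TGF-beta signaling pathway used for
# pathway-relatedness demonstration: ligands, receptors, SMAD transducers
# and the SAR1A trafficking component.
SAR1A
SMAD2
SMAD3
SMAD4
TGFB2
TGFB3
TGFBR1
TGFBR2
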