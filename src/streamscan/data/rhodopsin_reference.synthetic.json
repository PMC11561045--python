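{
 "description": "Synthetic helix-C reference segment of a proton-pumping Type I rhodopsin construct (package generator, seed 0); offsets are 0-based indices of the D/T/E proton-transfer residues and the spectral-tuning site within the segment.",
 "segment": "REEQRNEEVLVIVDVVLTILLIIVEIVQRQQRQNE",
 "d_offset": 13,
 "t_offset": 17,
 "e_offset": 24,
 "tuning_offset": 20
}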