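element_name	iupac	both_strands
ABRE	ACGTG	true
HSE	AGAANNTTCT	true
MBS	CAACTG	true
TC-rich	ATTTTCTTCA	true
TCA-element	CCATCTTTTT	true
W-box	TTGACY	true
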