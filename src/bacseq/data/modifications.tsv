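# Oligonucleotide end-modification absorbance contributions at 260 nm
# (editable).  name	epsilon260 (L/(mol*cm))
FAM	20960
HEX	31580
TET	16255
TAMRA	31980
ROX	22600
Cy3	4930
Cy5	10000
BHQ1	8000
BHQ2	8000
Biotin	0
Phosphate	0
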