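# pKa values of ionizable protein groups (EMBOSS-style defaults, editable).
# group	pK
Nterm	8.6
Cterm	3.6
D	3.9
E	4.1
C	8.5
Y	10.1
H	6.5
K	10.8
R	12.5
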