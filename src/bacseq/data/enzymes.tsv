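# Restriction enzyme recognition sites (editable).
# name	site (IUPAC, 5'->3')
EcoRI	GAATTC
BamHI	GGATCC
HindIII	AAGCTT
NotI	GCGGCCGC
XhoI	CTCGAG
SalI	GTCGAC
PstI	CTGCAG
SmaI	CCCGGG
KpnI	GGTACC
SacI	GAGCTC
NdeI	CATATG
NcoI	CCATGG
XbaI	TCTAGA
SpeI	ACTAGT
AvaII	GGWCC
HinfI	GANTC
EcoRV	GATATC
BglII	AGATCT
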