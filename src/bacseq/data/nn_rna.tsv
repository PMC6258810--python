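# RNA nearest-neighbor parameters (Watson-Crick propagation steps, 1 M NaCl).
# key = top-strand dinucleotide 5'->3' (RNA alphabet, T accepted as U);
# dH kcal/mol; dS cal/(mol*K).
# init = duplex initiation; term_AU = per terminal A-U pair penalty.
# hairpin_dG37_<n> = hairpin loop initiation free energy for loop size n;
# larger loops extrapolated as dG(9) + 1.75*R*T*ln(n/9).
AA	-6.82	-19.0
AC	-11.40	-29.5
AG	-10.48	-27.1
AU	-9.38	-26.7
CA	-10.44	-26.9
CC	-13.39	-32.7
CG	-10.64	-26.7
CU	-10.48	-27.1
GA	-12.44	-32.5
GC	-14.88	-36.9
GG	-13.39	-32.7
GU	-11.40	-29.5
UA	-7.69	-20.5
UC	-12.44	-32.5
UG	-10.44	-26.9
UU	-6.82	-19.0
init	3.61	-1.5
term_AU	3.72	10.5
symmetry	0.0	-1.4
hairpin_dG37_3	5.4	-
hairpin_dG37_4	5.6	-
hairpin_dG37_5	5.7	-
hairpin_dG37_6	5.4	-
hairpin_dG37_7	6.0	-
hairpin_dG37_8	5.5	-
hairpin_dG37_9	6.4	-
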