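# Undesirable chemical patterns: molecules matching any pattern receive a
# drug-likeliness score of exactly 0 during reward evaluation.  Editable
# starter list; one SMARTS<tab>label per line.
[N+](=O)[O-]	nitro_group
N=[N+]=[N-]	azide
OO	peroxide
[SH]	thiol
[NX3][NX3]	hydrazine
[CX3](=O)[F,Cl,Br,I]	acyl_halide
C=C=C	allene
[C-,N-,O-,S-]	bare_anion
[c;$(c1ccccc1)][N;R0]=[N;R0][c;$(c1ccccc1)]	azobenzene
C1OC1	epoxide
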