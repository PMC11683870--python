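# Structural alert substructures used by the "structural alerts" descriptor.
# Small curated starter catalogue of reactive/toxicophoric groups; users may
# replace the file with a house catalogue.  Format: SMARTS<tab>label
[N+](=O)[O-]	nitro_group
N=[N+]=[N-]	azide
[CX3](=O)[F,Cl,Br,I]	acyl_halide
[CX3H1]=O	aldehyde
C1OC1	epoxide
[NX3][NX3]	hydrazine
[SH]	thiol
OO	peroxide
[CX3]=[CX3][CX3]=O	michael_acceptor
[N;R0]=[N;R0]	azo_group
C(=S)N	thioamide
[Cl,Br,I][CH2]	alkyl_halide_primary
[C;R0](=O)[C;R0](=O)	alpha_diketone
[SX2][SX2]	disulfide
[CX3](=O)O[CX3](=O)	anhydride
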