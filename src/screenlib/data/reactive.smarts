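# Reactive functional groups: electrophiles and unstable moieties that
# consume assay reagents or modify proteins non-specifically.
# Format: name<TAB>SMARTS<TAB>active
acyl_halide	[CX3](=O)[F,Cl,Br,I]	1
sulfonyl_halide	[SX4](=O)(=O)[F,Cl,Br]	1
primary_alkyl_halide	[CH2X4][Br,I]	1
alpha_halo_carbonyl	[CX3](=O)[CX4][F,Cl,Br,I]	1
aldehyde	[CX3H1](=O)[#6]	1
epoxide	C1OC1	1
aziridine	C1NC1	1
isocyanate	[NX2]=C=O	1
isothiocyanate	[NX2]=C=S	1
acid_anhydride	[CX3](=O)O[CX3](=O)	1
thiol	[SX2H]	1
peroxide	[OX2][OX2]	1
azide	N=[N+]=[N-]	1
diazonium	[#6][N+]#N	1
hydrazine	[NX3][NX3;H2]	1
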