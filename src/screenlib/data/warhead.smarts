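# Warheads: covalent-modifier motifs (Michael acceptors and related
# protein-reactive electrophiles) flagged for HTS triage.
# Format: name<TAB>SMARTS<TAB>active
michael_ketone	[CX3]=[CX3][CX3]=[OX1]	1
vinyl_sulfone	C=C[SX4](=O)=O	1
acrylonitrile	C=CC#N	1
acrylamide	C=C[CX3](=O)[NX3]	1
acrylate_ester	C=C[CX3](=O)O[#6]	1
propiolamide	C#C[CX3](=O)[NX3]	1
haloacetamide	[NX3][CX3](=O)[CH2][Cl,Br,I]	1
chloromethyl_ketone	[CX3](=O)[CH2]Cl	1
boronic_acid	[BX3]([OX2H])[OX2H]	1
beta_lactam	O=C1[CX4][CX4]N1	1
beta_lactone	O=C1OCC1	1
nitroalkene	C=C[N+](=O)[O-]	1
quinone_methide	C=C1C=CC(=O)C=C1	1
sulfonate_ester	[#6]O[SX4](=O)(=O)[#6]	1
fluorophosphate	[PX4](=O)F	1
cyanamide	[NX3]C#N	1
vinyl_sulfonamide	C=C[SX4](=O)(=O)[NX3]	1
alkynyl_ketone	C#C[CX3](=O)[#6]	1
disulfide	[SX2][SX2]	1
maleimide	O=C1C=CC(=O)N1	1
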