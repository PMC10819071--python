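name	smarts	include_h
hydroxyl	[OX2H1]	1
amino	[NX3;H2;!$(NC=O)]	1
methyl	[CX4H3]	1
carboxyl	[CX3](=O)[OX2H1]	1
carbonyl	[CX3]=[OX1]	0
nitro	[$([NX3](=O)=O),$([NX3+](=O)[O-])]	0
ester	[CX3](=O)[OX2][#6]	0
amide	[CX3](=O)[NX3]	1
ether	[OD2]([#6])[#6]	0
thiol	[SX2H1]	1
halogen	[F,Cl,Br,I]	0
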