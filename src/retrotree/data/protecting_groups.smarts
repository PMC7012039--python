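# Default functional/protecting-group library (~75 entries).
# Two tab-separated columns: name, SMARTS.  Variable-length variants
# (silyl/ester alkyl chains) are matched by a representative core pattern;
# users may replace this file with their own via the groups option.
boc_carbamate	CC(C)(C)OC(=O)[NX3]
cbz_carbamate	O=C(OCc1ccccc1)[NX3]
fmoc_carbamate	O=C([NX3])OCC1c2ccccc2-c2ccccc21
troc_carbamate	O=C(OCC(Cl)(Cl)Cl)[NX3]
alloc_carbamate	C=CCOC(=O)[NX3]
methyl_carbamate	[CH3]OC(=O)[NX3]
n_acetyl	[CH3]C(=O)[NX3]
n_trifluoroacetyl	FC(F)(F)C(=O)[NX3]
n_benzoyl	O=C([NX3])c1ccccc1
o_acetyl	[CH3]C(=O)[OX2]
o_pivaloyl	CC(C)(C)C(=O)[OX2]
o_benzoyl	O=C([OX2])c1ccccc1
benzyl_ether	[OX2;$(OC)]Cc1ccccc1
pmb_ether	[CH3]Oc1ccc(C[OX2])cc1
trityl	C(c1ccccc1)(c1ccccc1)c1ccccc1
tms_ether	[CH3][Si]([CH3])([CH3])[OX2]
tbs_ether	CC(C)(C)[Si]([CH3])([CH3])[OX2]
tips_ether	[Si](C(C)C)(C(C)C)C(C)C
tbdps_ether	CC(C)(C)[Si](c1ccccc1)(c1ccccc1)[OX2]
thp_ether	[OX2]C1CCCCO1
mom_ether	[CH3]OC([H])([H])[OX2]
allyl_ether	C=CC[OX2;$(OC)]
dimethyl_acetal	[CH3][OX2]C[OX2][CH3]
cyclic_acetal	C1[OX2]CC[OX2]1
acetonide	CC1(C)[OX2]CC[OX2]1
mesylate	CS(=O)(=O)[OX2]
tosylate	Cc1ccc(cc1)S(=O)(=O)[OX2]
triflate	[OX2]S(=O)(=O)C(F)(F)F
nosyl_sulfonamide	O=S(=O)(c1ccc(cc1)[N+](=O)[O-])[NX3]
phthalimide	O=C1c2ccccc2C(=O)N1
maleimide	O=C1C=CC(=O)N1
carboxylic_acid	[CX3](=O)[OX2H1]
methyl_ester	[CX3](=O)[OX2][CH3]
ethyl_ester	[CX3](=O)[OX2][CH2][CH3]
tbu_ester	[CX3](=O)[OX2]C([CH3])([CH3])[CH3]
benzyl_ester	[CX3](=O)[OX2]Cc1ccccc1
ester	[CX3](=O)[OX2][CX4]
amide	[CX3](=O)[NX3]
lactam	O=C1CCCN1
lactone	O=C1CCCO1
anhydride	[CX3](=O)[OX2][CX3](=O)
acyl_chloride	[CX3](=O)Cl
aldehyde	[CX3H1]=O
ketone	[#6][CX3](=O)[#6]
nitrile	[CX2]#[NX1]
nitro	[N+](=O)[O-]
primary_amine	[NX3;H2][CX4]
secondary_amine	[NX3;H1]([CX4])[CX4]
tertiary_amine	[NX3]([CX4])([CX4])[CX4]
aniline	[NX3;H2]c
hydroxyl	[OX2H1][CX4]
phenol	[OX2H1]c
ether	[OX2]([CX4])[CX4]
thiol	[SX2H1]
thioether	[SX2]([#6])[#6]
sulfoxide	[SX3](=O)([#6])[#6]
sulfone	[SX4](=O)(=O)([#6])[#6]
sulfonamide	[SX4](=O)(=O)[NX3]
sulfonyl_chloride	S(=O)(=O)Cl
carbamate	[NX3][CX3](=O)[OX2]
urea	[NX3][CX3](=O)[NX3]
guanidine	[NX3][CX3](=[NX2])[NX3]
imine	[CX3]=[NX2]
oxime	[CX3]=[NX2][OX2H1]
hydrazone	[CX3]=[NX2][NX3]
azide	[NX2]=[N+]=[N-]
isocyanate	[NX2]=C=O
isothiocyanate	[NX2]=C=S
epoxide	C1OC1
aziridine	C1NC1
alkene	[CX3]=[CX3]
alkyne	[CX2]#[CX2]
aryl_fluoride	cF
aryl_chloride	cCl
aryl_bromide	cBr
aryl_iodide	cI
alkyl_bromide	[CX4][Br]
alkyl_chloride	[CX4][Cl]
alkyl_iodide	[CX4][I]
boronic_acid	[BX3]([OX2H1])[OX2H1]
pinacol_boronate	[BX3]1[OX2]C([CH3])([CH3])C([CH3])([CH3])[OX2]1
phosphate	P(=O)([OX2])([OX2])[OX2]
phosphonate	[CX4]P(=O)([OX2])[OX2]
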