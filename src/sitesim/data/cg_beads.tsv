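aa3	bead_index	members	class
ALA	0	CA	NONPOLAR
ALA	1	CB	HYDROPHOBIC
ARG	0	CA	NONPOLAR
ARG	1	CB,CG,CD	HYDROPHOBIC
ARG	2	NE,CZ,NH1,NH2	POSITIVE
ASN	0	CA	NONPOLAR
ASN	1	CB,CG,OD1,ND2	POLAR
ASP	0	CA	NONPOLAR
ASP	1	CB,CG,OD1,OD2	NEGATIVE
CYS	0	CA	NONPOLAR
CYS	1	CB,SG	POLAR
GLN	0	CA	NONPOLAR
GLN	1	CB,CG	HYDROPHOBIC
GLN	2	CD,OE1,NE2	POLAR
GLU	0	CA	NONPOLAR
GLU	1	CB,CG	NONPOLAR
GLU	2	CD,OE1,OE2	NEGATIVE
GLY	0	CA	NONPOLAR
HIS	0	CA	NONPOLAR
HIS	1	CB,CG	POSITIVE
HIS	2	ND1,CD2,CE1,NE2	POSITIVE
ILE	0	CA	NONPOLAR
ILE	1	CB,CG1,CG2,CD1	HYDROPHOBIC
LEU	0	CA	NONPOLAR
LEU	1	CB,CG,CD1,CD2	HYDROPHOBIC
LYS	0	CA	NONPOLAR
LYS	1	CB,CG,CD	HYDROPHOBIC
LYS	2	CE,NZ	POSITIVE
MET	0	CA	NONPOLAR
MET	1	CB,CG	NONPOLAR
MET	2	SD,CE	POLAR
PHE	0	CA	NONPOLAR
PHE	1	CB,CG	HYDROPHOBIC
PHE	2	CD1,CD2,CE1,CE2,CZ	HYDROPHOBIC
PRO	0	CA	NONPOLAR
PRO	1	CB,CG	HYDROPHOBIC
PRO	2	CD	NONPOLAR
SER	0	CA	NONPOLAR
SER	1	CB,OG	POLAR
THR	0	CA	NONPOLAR
THR	1	CB,OG1,CG2	POLAR
TRP	0	CA	NONPOLAR
TRP	1	CB,CG,CD1,CD2	HYDROPHOBIC
TRP	2	NE1,CE2,CE3,CZ2,CZ3,CH2	HYDROPHOBIC
TYR	0	CA	NONPOLAR
TYR	1	CB,CG,CD1,CD2	HYDROPHOBIC
TYR	2	CE1,CE2,CZ,OH	HYDROPHOBIC
VAL	0	CA	NONPOLAR
VAL	1	CB,CG1,CG2	HYDROPHOBIC
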