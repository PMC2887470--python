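aa3	atom	class
ALA	N	POLAR
ALA	CA	NONPOLAR
ALA	C	NONPOLAR
ALA	O	POLAR
ALA	CB	HYDROPHOBIC
ARG	N	POLAR
ARG	CA	NONPOLAR
ARG	C	NONPOLAR
ARG	O	POLAR
ARG	CB	HYDROPHOBIC
ARG	CG	HYDROPHOBIC
ARG	CD	NONPOLAR
ARG	NE	POSITIVE
ARG	CZ	POSITIVE
ARG	NH1	POSITIVE
ARG	NH2	POSITIVE
ASN	N	POLAR
ASN	CA	NONPOLAR
ASN	C	NONPOLAR
ASN	O	POLAR
ASN	CB	HYDROPHOBIC
ASN	CG	NONPOLAR
ASN	OD1	POLAR
ASN	ND2	POLAR
ASP	N	POLAR
ASP	CA	NONPOLAR
ASP	C	NONPOLAR
ASP	O	POLAR
ASP	CB	NONPOLAR
ASP	CG	NEGATIVE
ASP	OD1	NEGATIVE
ASP	OD2	NEGATIVE
CYS	N	POLAR
CYS	CA	NONPOLAR
CYS	C	NONPOLAR
CYS	O	POLAR
CYS	CB	NONPOLAR
CYS	SG	POLAR
GLN	N	POLAR
GLN	CA	NONPOLAR
GLN	C	NONPOLAR
GLN	O	POLAR
GLN	CB	HYDROPHOBIC
GLN	CG	HYDROPHOBIC
GLN	CD	NONPOLAR
GLN	OE1	POLAR
GLN	NE2	POLAR
GLU	N	POLAR
GLU	CA	NONPOLAR
GLU	C	NONPOLAR
GLU	O	POLAR
GLU	CB	HYDROPHOBIC
GLU	CG	NONPOLAR
GLU	CD	NEGATIVE
GLU	OE1	NEGATIVE
GLU	OE2	NEGATIVE
GLY	N	POLAR
GLY	CA	NONPOLAR
GLY	C	NONPOLAR
GLY	O	POLAR
HIS	N	POLAR
HIS	CA	NONPOLAR
HIS	C	NONPOLAR
HIS	O	POLAR
HIS	CB	NONPOLAR
HIS	CG	POSITIVE
HIS	ND1	POSITIVE
HIS	CD2	POSITIVE
HIS	CE1	POSITIVE
HIS	NE2	POSITIVE
ILE	N	POLAR
ILE	CA	NONPOLAR
ILE	C	NONPOLAR
ILE	O	POLAR
ILE	CB	HYDROPHOBIC
ILE	CG1	HYDROPHOBIC
ILE	CG2	HYDROPHOBIC
ILE	CD1	HYDROPHOBIC
LEU	N	POLAR
LEU	CA	NONPOLAR
LEU	C	NONPOLAR
LEU	O	POLAR
LEU	CB	HYDROPHOBIC
LEU	CG	HYDROPHOBIC
LEU	CD1	HYDROPHOBIC
LEU	CD2	HYDROPHOBIC
LYS	N	POLAR
LYS	CA	NONPOLAR
LYS	C	NONPOLAR
LYS	O	POLAR
LYS	CB	HYDROPHOBIC
LYS	CG	HYDROPHOBIC
LYS	CD	HYDROPHOBIC
LYS	CE	POSITIVE
LYS	NZ	POSITIVE
MET	N	POLAR
MET	CA	NONPOLAR
MET	C	NONPOLAR
MET	O	POLAR
MET	CB	HYDROPHOBIC
MET	CG	NONPOLAR
MET	SD	POLAR
MET	CE	NONPOLAR
PHE	N	POLAR
PHE	CA	NONPOLAR
PHE	C	NONPOLAR
PHE	O	POLAR
PHE	CB	HYDROPHOBIC
PHE	CG	HYDROPHOBIC
PHE	CD1	HYDROPHOBIC
PHE	CD2	HYDROPHOBIC
PHE	CE1	HYDROPHOBIC
PHE	CE2	HYDROPHOBIC
PHE	CZ	HYDROPHOBIC
PRO	N	POLAR
PRO	CA	NONPOLAR
PRO	C	NONPOLAR
PRO	O	POLAR
PRO	CB	HYDROPHOBIC
PRO	CG	HYDROPHOBIC
PRO	CD	NONPOLAR
SER	N	POLAR
SER	CA	NONPOLAR
SER	C	NONPOLAR
SER	O	POLAR
SER	CB	NONPOLAR
SER	OG	POLAR
THR	N	POLAR
THR	CA	NONPOLAR
THR	C	NONPOLAR
THR	O	POLAR
THR	CB	NONPOLAR
THR	OG1	POLAR
THR	CG2	HYDROPHOBIC
TRP	N	POLAR
TRP	CA	NONPOLAR
TRP	C	NONPOLAR
TRP	O	POLAR
TRP	CB	HYDROPHOBIC
TRP	CG	HYDROPHOBIC
TRP	CD1	NONPOLAR
TRP	CD2	HYDROPHOBIC
TRP	NE1	POLAR
TRP	CE2	NONPOLAR
TRP	CE3	HYDROPHOBIC
TRP	CZ2	HYDROPHOBIC
TRP	CZ3	HYDROPHOBIC
TRP	CH2	HYDROPHOBIC
TYR	N	POLAR
TYR	CA	NONPOLAR
TYR	C	NONPOLAR
TYR	O	POLAR
TYR	CB	HYDROPHOBIC
TYR	CG	HYDROPHOBIC
TYR	CD1	HYDROPHOBIC
TYR	CD2	HYDROPHOBIC
TYR	CE1	HYDROPHOBIC
TYR	CE2	HYDROPHOBIC
TYR	CZ	NONPOLAR
TYR	OH	POLAR
VAL	N	POLAR
VAL	CA	NONPOLAR
VAL	C	NONPOLAR
VAL	O	POLAR
VAL	CB	HYDROPHOBIC
VAL	CG1	HYDROPHOBIC
VAL	CG2	HYDROPHOBIC
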