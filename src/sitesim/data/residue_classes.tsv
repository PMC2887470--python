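aa3	class
LYS	POSITIVE
ARG	POSITIVE
HIS	POSITIVE
ASP	NEGATIVE
GLU	NEGATIVE
SER	POLAR
THR	POLAR
ASN	POLAR
GLN	POLAR
CYS	POLAR
GLY	NONPOLAR
ALA	NONPOLAR
PRO	NONPOLAR
VAL	HYDROPHOBIC
LEU	HYDROPHOBIC
ILE	HYDROPHOBIC
MET	HYDROPHOBIC
PHE	HYDROPHOBIC
TRP	HYDROPHOBIC
TYR	HYDROPHOBIC
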