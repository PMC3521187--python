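# Number of rotatable single bonds (chi angles) in each side chain.
residue	rotatable_bonds
ALA	0
ARG	4
ASN	2
ASP	2
CYS	1
GLN	3
GLU	3
GLY	0
HIS	2
ILE	2
LEU	2
LYS	4
MET	3
PHE	2
PRO	0
SER	1
THR	1
TRP	2
TYR	2
VAL	1
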