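# Per-residue physicochemical sequence properties (20 standard amino acids).
# atom_count: number of heavy (non-hydrogen) atoms, backbone included.
# eiip: electron-ion interaction potential (Veljkovic et al.), Rydberg units.
# hydrophobicity: Kyte-Doolittle hydropathy index.
# hydrophilicity: Hopp-Woods hydrophilicity scale.
# propensity: Chou-Fasman alpha-helix conformational propensity P_alpha
#   (the literature does not pin down which propensity is meant for hot-spot
#   work; this is the implementer's documented choice, override with --seq-table).
# isoelectric_point: pI of the free amino acid, pH units (Lehninger).
residue	atom_count	eiip	hydrophobicity	hydrophilicity	propensity	isoelectric_point
ALA	5	0.0373	1.8	-0.5	1.42	6.00
ARG	11	0.0959	-4.5	3.0	0.98	10.76
ASN	8	0.0036	-3.5	0.2	0.67	5.41
ASP	8	0.1263	-3.5	3.0	1.01	2.77
CYS	6	0.0829	2.5	-1.0	0.70	5.07
GLN	9	0.0761	-3.5	0.2	1.11	5.65
GLU	9	0.0058	-3.5	3.0	1.51	3.22
GLY	4	0.0050	-0.4	0.0	0.57	5.97
HIS	10	0.0242	-3.2	-0.5	1.00	7.59
ILE	8	0.0000	4.5	-1.8	1.08	6.02
LEU	8	0.0000	3.8	-1.8	1.21	5.98
LYS	9	0.0371	-3.9	3.0	1.16	9.74
MET	8	0.0823	1.9	-1.3	1.45	5.74
PHE	11	0.0946	2.8	-2.5	1.13	5.48
PRO	7	0.0198	-1.6	0.0	0.57	6.30
SER	6	0.0829	-0.8	0.3	0.77	5.68
THR	7	0.0941	-0.7	-0.4	0.83	5.60
TRP	14	0.0548	-0.9	-3.4	1.08	5.89
TYR	12	0.0516	-1.3	-2.3	0.69	5.66
VAL	7	0.0057	4.2	-1.5	1.06	5.96
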