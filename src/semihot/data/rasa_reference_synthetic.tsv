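# SYNTHETIC per-attribute reference ASA table for RASA normalisation, A^2.
# Constructed, not measured: 'total' is the theoretical Gly-X-Gly maxASA
# (Tien et al. 2013); 'backbone' is a nominal extended-tripeptide backbone
# exposure (40 A^2; all of 'total' for Gly); 'side_chain' = total - backbone;
# 'polar'/'non_polar' split 'total' by the residue's heavy-atom composition
# (N+O vs C; sulfur counts to neither). Override with a measured table via
# configuration if exact PSAIA/NACCESS-compatible references are required.
residue	total	backbone	side_chain	polar	non_polar
ALA	129.0	40.0	89.0	51.6	77.4
ARG	274.0	40.0	234.0	124.5	149.5
ASN	195.0	40.0	155.0	97.5	97.5
ASP	193.0	40.0	153.0	96.5	96.5
CYS	167.0	40.0	127.0	55.7	83.5
GLN	225.0	40.0	185.0	100.0	125.0
GLU	223.0	40.0	183.0	99.1	123.9
GLY	104.0	104.0	0.0	52.0	52.0
HIS	224.0	40.0	184.0	89.6	134.4
ILE	197.0	40.0	157.0	49.2	147.8
LEU	201.0	40.0	161.0	50.2	150.8
LYS	236.0	40.0	196.0	78.7	157.3
MET	224.0	40.0	184.0	56.0	140.0
PHE	240.0	40.0	200.0	43.6	196.4
PRO	159.0	40.0	119.0	45.4	113.6
SER	155.0	40.0	115.0	77.5	77.5
THR	172.0	40.0	132.0	73.7	98.3
TRP	285.0	40.0	245.0	61.1	223.9
TYR	263.0	40.0	223.0	65.8	197.2
VAL	174.0	40.0	134.0	49.7	124.3
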