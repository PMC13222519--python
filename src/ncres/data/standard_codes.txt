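# Curated subset of standard three-letter component codes used for
# collision checks when assigning custom component IDs. Covers the 20
# canonical residues, common modified residues, and the ids shipped in the
# synthetic mini component library. Not the full dictionary.
ALA
ARG
ASN
ASP
CYS
GLN
GLU
GLY
HIS
ILE
LEU
LYS
MET
PHE
PRO
SER
THR
TRP
TYR
VAL
# common modified residues
MSE
SEP
TPO
PTR
HYP
PCA
CSO
KCX
LLP
MLY
M3L
CME
CSD
OCS
ALY
FME
DAL
DAR
DSN
DPR
AIB
ABU
NLE
ORN
DAB
# mini-library fixture ids not covered above
BAL
GAB
ACY
ACT
BNZ
EOH
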