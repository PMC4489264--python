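# atom-type classes: 1 aliphatic C, 2 aromatic C, 3 polar N, 4 charged N,
# 5 polar O, 6 charged O, 7 S, 8 other. Wildcard rows (*, element) are fallbacks.
resname,atom_name,atom_class
ALA,N,3
ALA,CA,1
ALA,C,1
ALA,O,5
ALA,OXT,6
ALA,CB,1
ARG,N,3
ARG,CA,1
ARG,C,1
ARG,O,5
ARG,OXT,6
ARG,CB,1
ARG,CG,1
ARG,CD,1
ARG,NE,4
ARG,CZ,1
ARG,NH1,4
ARG,NH2,4
ASN,N,3
ASN,CA,1
ASN,C,1
ASN,O,5
ASN,OXT,6
ASN,CB,1
ASN,CG,1
ASN,OD1,5
ASN,ND2,3
ASP,N,3
ASP,CA,1
ASP,C,1
ASP,O,5
ASP,OXT,6
ASP,CB,1
ASP,CG,1
ASP,OD1,6
ASP,OD2,6
CYS,N,3
CYS,CA,1
CYS,C,1
CYS,O,5
CYS,OXT,6
CYS,CB,1
CYS,SG,7
GLN,N,3
GLN,CA,1
GLN,C,1
GLN,O,5
GLN,OXT,6
GLN,CB,1
GLN,CG,1
GLN,CD,1
GLN,OE1,5
GLN,NE2,3
GLU,N,3
GLU,CA,1
GLU,C,1
GLU,O,5
GLU,OXT,6
GLU,CB,1
GLU,CG,1
GLU,CD,1
GLU,OE1,6
GLU,OE2,6
GLY,N,3
GLY,CA,1
GLY,C,1
GLY,O,5
GLY,OXT,6
HIS,N,3
HIS,CA,1
HIS,C,1
HIS,O,5
HIS,OXT,6
HIS,CB,1
HIS,CG,2
HIS,ND1,3
HIS,CD2,2
HIS,CE1,2
HIS,NE2,3
ILE,N,3
ILE,CA,1
ILE,C,1
ILE,O,5
ILE,OXT,6
ILE,CB,1
ILE,CG1,1
ILE,CG2,1
ILE,CD1,1
LEU,N,3
LEU,CA,1
LEU,C,1
LEU,O,5
LEU,OXT,6
LEU,CB,1
LEU,CG,1
LEU,CD1,1
LEU,CD2,1
LYS,N,3
LYS,CA,1
LYS,C,1
LYS,O,5
LYS,OXT,6
LYS,CB,1
LYS,CG,1
LYS,CD,1
LYS,CE,1
LYS,NZ,4
MET,N,3
MET,CA,1
MET,C,1
MET,O,5
MET,OXT,6
MET,CB,1
MET,CG,1
MET,SD,7
MET,CE,1
PHE,N,3
PHE,CA,1
PHE,C,1
PHE,O,5
PHE,OXT,6
PHE,CB,1
PHE,CG,2
PHE,CD1,2
PHE,CD2,2
PHE,CE1,2
PHE,CE2,2
PHE,CZ,2
PRO,N,3
PRO,CA,1
PRO,C,1
PRO,O,5
PRO,OXT,6
PRO,CB,1
PRO,CG,1
PRO,CD,1
SER,N,3
SER,CA,1
SER,C,1
SER,O,5
SER,OXT,6
SER,CB,1
SER,OG,5
THR,N,3
THR,CA,1
THR,C,1
THR,O,5
THR,OXT,6
THR,CB,1
THR,OG1,5
THR,CG2,1
TRP,N,3
TRP,CA,1
TRP,C,1
TRP,O,5
TRP,OXT,6
TRP,CB,1
TRP,CG,2
TRP,CD1,2
TRP,CD2,2
TRP,NE1,3
TRP,CE2,2
TRP,CE3,2
TRP,CZ2,2
TRP,CZ3,2
TRP,CH2,2
TYR,N,3
TYR,CA,1
TYR,C,1
TYR,O,5
TYR,OXT,6
TYR,CB,1
TYR,CG,2
TYR,CD1,2
TYR,CD2,2
TYR,CE1,2
TYR,CE2,2
TYR,CZ,2
TYR,OH,5
VAL,N,3
VAL,CA,1
VAL,C,1
VAL,O,5
VAL,OXT,6
VAL,CB,1
VAL,CG1,1
VAL,CG2,1
*,C,1
*,N,3
*,O,5
*,S,7
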