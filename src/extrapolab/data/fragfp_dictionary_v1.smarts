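# extrapolab fragment dictionary
# {"corpus_id": "degradation-union-seed20240101", "corpus_size": 900, "max_atoms": 7, "corr_threshold": 0.8, "min_frequency": 0.02}
CC
N
CN
C=C
CCC
CCN
O
C=CC=C
CNC
CC=CC
CCCC
C=CN
CCO
CCNC
C=CC=CC
CCCCC
CCCN
C=N
C=CCC
C=O
C=CNC
C=CCN
CCCO
C=CC=CN
COC
C=C(C)N
C=CCNC
C=CCO
CCOP
CC=CNCC
CCCCN
NCN
C/C=C/C
CC=CCN
CC=CCC
C=C(C)C
CCCCCO
CCNCC
CCC=N
NC=O
C=CO
CN(C)C
C=CNCCC
CC(C)O
CCC=O
CC[C@@H](C)O
OCCO
CCCCCNC
CCCOP
C=CC=C(C)N
C=CC=CC=C
CCO[PH2](N)O
CC(C)=N
F
C=C(C)NC
C=CC(=C)C
C=CC=N
C=CCCCCC
COCCN
CCC=CN
CNCO
CC=CCNCC
CNCN
C=CC=CNC
CC=CC=CC
NN
N=CN
C=CC(=C)N
CC=C/C=C/C
CCCNCC
CC=NC
CCCC=O
CCCN(C)C
NCC=O
NCCN
OCCCO
C=COP
CC(N)=O
CC=C(C)CC
C=CCC=N
CC(=O)O
C=CC=CCC
C=CN(C)CC
CC=CCO
CCCOC
C=C(C)O
C/C=C/C=CN
CC=CN(C)C
CCC[C@@H](C)O
CO[PH2]NCCO
C=CC=CO
C=CCCN
C=CCOP
NS
C=CNC=O
CN(C)C=O
N[PH2](O)OCCO
C=NCC
CC=C(C)NCC
C=CC=CCN
CCC=C(C)N
CCCO[PH2](N)O
CCN(C)CC
NCCCCCO
CC=CCCC
CC[C@H](C)O
CC=C(C)C=N
CC=CC(C)=N
C[C@H](O)CO
C=C(C)C(C)=N
C=CNN
C=CC(=C)NC
C=CNCO
C=CCNCCN
CCO[PH2]OCC
C[C@H](N)O
C=NNCC
CCCCNCC
CCCNC=O
CC[C@H](O)CCO
COC(C)C
C=CC(=C)C=N
C=CC=O
O=CCNP
C=CC=NC
C=C(C)CCC
C=CCNC=C
CCOCCOP
OCCCCCO
CC(C)C
C=CO[PH2](N)O
C[C@@H](O)CCO
O=P
c
CCNCN
CN=C(C)C
C=CC(C)=CN
CC(C)N
CN(C)N
C=C(C)OP
CCCCCCO
C=CCNC=O
CCCCCC=O
OCCF
CC=C(C)O
CC=CC=CN
N=C(N)N
C=CCC=C
C=C(C)NCCC
C=CC=C(N)C=C
CCNC(C)=O
C=CC=C(C)NC
C=CCCC=C
CCC=CNC
N=CNS
NCNCO
CCC=C(C)C
C=C(N)CN
C=C[C@@H](O)CC
CC=NC=N
C=CC(=N)CC
CCCN(C)CC
C=CCC(=N)CC
CC=CCOP
CCCCF
NCCF
OCCCOP
C/C=C/CCCO
C=CC=CCO
C=NCNS
CN(C)CO
CNCNC
CS
CC=CC(N)=CC
CC=CCCN
C=CCNN
C=C(C)N(C)C
C=CNC=C
CCCC=N
C=CC=C/C=C/C
C=NCCC
CCOC(C)C
C=CC=C(C)C
C=CC=CCCC
C=CC=CN(C)C
C=CCCNC
CCC=CCN
CNC=CCN
C=C(C)NN
CC=C(C)C=NC
CCCOCCO
C=CC=COP
CC[C@@H](C)OC
C=C(N)C=CCN
C=C(N)CC
C=CN(C=O)CC
C=NNC=CC
CC=CNCOC
CC=CO[PH2](N)O
CCOPOCC
CN(C)CN
NCN[SH]=O
CC[C@@H](O)CC
CN(C)CCN
C=CC(=CC)NC
C=CC(=O)NC
C=CNC(C)=O
C=CCNCC=C
C=C(C)NC=O
C=C(C)NCCN
CC(C)CN
CCC(N)=O
CCC=NNC
CCCO[P@@](N)=O
COPNCC=O
NC=CC=CO
C=COP=O
CC=CC(C)=NC
CCCC(C)=CN
C=CCNC(=C)C
CNC=CC=O
COPOCCO
C=C(C)CCN
C=CC(=C)OP
CC=CN(C)N
CC=NN(C)C
CCCCNCN
NCC=CCO
C=CCN=C
C=NNCCN
CC(C)=NN
CCNCCNN
C[C@@H](C=O)NP
C=CCCC(=C)C
C=NC(C)=C(C)C
CC(C)CO
CCC[C@H](O)CO
CN(C)S
CNC=N
C[C@H](O)COP=O
C[C@H](O)CO[PH2]N
C=C(O)C=CC
C=CC=CNC=O
C=CCC=NC=N
C=CN[C@@H](C)O
C=CN[C@H](O)CC
CC=C(CN)NC
CCC=NC=NC
C[C@@H](O)NCN
N=C(N)NS
O=CNCO
C=CC(O)=CC
C=CC=CC=N
C=NCNC
CC(C)NP(O)O
CC(C)OCN
CC=CC=CO
NCCCCC=O
NCCCO
C=C(C)C=CC
CC(=O)N(C)C
CC=C(C)OP
CC=CC=CCC
CCN(CC)CC
CN=CN[SH]=O
CN[C@H](O)CF
cccn
C=CC=C(C)O
C=CN(C)COC
C=CNCC(=C)N
CCC=CNCC
CCCC(=O)O
CC[C@@H](O)CC=O
CN(C)CCF
CO[C@H](C)CO
N=CC/C=C/CO
C=CCC(=N)C=C
C=CF
C=CN(C)N=C
C=CN(CC)CC
C=COC
CC=C/C=C/CO
CC=CCC=CC
CCC=C(C)NC
CCN(N)CC
N=CCN
C=CC=CCOP
C=CC=CNN
C=CC=NCNS
C=CCC=CCC
CC=CC=CCN
CCC(O)CC
CCOCCF
CC[C@@H](O)CF
N=CC=CN
N=CC=O
NCC(N)=O
ccC
C=C(C)O[PH2](N)O
C=CNC(=C)CN
CC=CCNC=O
CC=CCO[PH2]N
CCC=CC(C)=N
CNC(N)=O
CNC=C(C)C
C[C@H](C)O
NPOCCCO
N[SH](=O)=O
C=CC=CC(=C)N
C=NC(N)=NCC
CC=CNC=CC
CC=CNCCF
CO[PH2]NCC=O
cN
C=C(CC)CC
C=CCOC
C=CN(N)CCN
CCCC(C)=N
CSNC=N
NCNCCF
C=C(C)N(C)N
C=C(C)N=CNS
C=CCN(C)N
C=NCNSC
CCC=CC=NC
CCN(C=O)CC
CCO[C@@H](C)CO
CNCC=CC=N
C=CC=CC=CN
C=CCN(C)C=O
C=CCNC(C)=O
CC=CN(C)CO
CC[C@@H](O)N(C)C
C[C@@H](O)CCF
O=CCCCCO
C=CCC(=C)C
C=CN=C(N)N
CC(=O)OC(C)C
CC(F)CN
CNCNCOC
C=C(CN)NCC
C=CC=CNC=C
C=CC=NN
C=CCO[P@@](N)=O
C=CN(C)CCN
CC(C)=CCN
CC(N)=CCCN
CC=CC=C(C)C
NC=C/C=C/CO
C=CC=CO[PH2]N
CC=CC=O
CC=CCCCC
CCCN=CNS
CCCOC(C)C
CNC=CCNC
CNCN(C)C
COCN(C)CN
C=CC(=C)NC=O
C=CNCCNN
C=CNN=CCC
CC(C)N[PH2](O)O
CCCNC(C)=O
C=CCCNCC
C=CCF
CCCC[C@H](N)O
CCNC(=O)CC
CCCCC(N)=O
CNC=CC(N)=O
CS(=O)NCN
cO
C=CN=CNC
N[SH3]
C=CCC=O
CCCC(=O)NC
CCCN=C(N)N
CCN=CNC
CC[C@@H](O)NC=O
CN(C)C=CC=O
CN(C)CCNN
CN(C=N)[SH]=O
CNCNC=O
NCC=CCCN
NNCC=O
O=[SH]
C=CN(CN)CO
C=CNCC(C)C
C=CNCC=O
C=NC(=C)C=CC
C=NC(=N)N[SH]=O
CC(C)CN(C)C
CC(C)CNCN
CC=CC=COP
CN(C)S(C)=O
CN=C(N)N[SH]=O
COCN(C)C=O
CO[C@H](C)N(C)C
C[C@@H](O)N(C)CN
NCCCCCN
O=CNCCF
C=CC(=C)NN
C=CC=NC=N
C=CN=CN=C
C=NCN(C)[SH]=O
C=NNC(C)=CC
CC(C)[C@H](N)O
CC=CCOP=O
CCOCCCO
CN[C@H](O)CCO
N[PH2]OCCCO
C=C(C)CN
C=C(C)OC
C=CC(N)=C(C)C
C=CC=CN(C)N
C=CCCN=C
C=CCN(C)C=C
C=CCN=C(N)N
CC=CC=CC=N
CCNCNCC
CN(C)CCCO
CN=C(N)NC
cCN
cccnc
C=C(N)C=O
C=CC=CCN=C
C=CCC=C(C)C
C=CNC=C(C)C
CC=CC=CCO
CCC(C)CO
CCC=CNN
CN(C)[SH](=O)=O
CNC(C)=C(C)C
CNCCCCO
COC=CC=CN
NCNCCCO
C=CC=C(O)C=C
C=CN=CNSC
CC=C(C)OP=O
CC=CCC=N
CC=NC(=N)NC
CCC(=N)C=O
CCNCC=O
COCC=CCN
CccCC
Cn
O=CNCCCO
C=C(C)C=C(C)C
C=CCN=CNS
C=CN(C)[C@@H](C)O
C=CNC(=O)C=C
C=CNN=CCN
CC(C)CNC=O
CC(C=O)=NN
CC=CC(C)=CC
CCC(=N)CN
CNCO[C@H](C)C
C1CCOC1
C=C(C=CC)OP
C=C(C=N)CC
C=C(N)C=CCO
C=CC(=CC)OP
C=CC=COP=O
C=CCC(=C)N
C=NCN[SH](=O)=O
CC(=N)C=CCN
CC(CN)=NN
CC=CN(C)CN
CCNCNCO
CC[C@H](O)COC
CN(C)C(=O)CN
CN(C)C=CCN
C=C(C)NC(=C)C
C=C(N)CN(C)C
C=CC(=O)NCC
C=CC(C)=NN
C=CN(N)C=C
C=CN=C(N)NS
C=CNC(=O)CC
C=Cc
CC(CO)CO
CCC=CC(N)=O
CCCCOCN
CCCNCCN
CCO[PH3]
COCNC(N)=O
COC[C@@H](O)CF
C=C(C)CC(=C)C
C=C(CN)NN
C=CC(=C)OP=O
C=CC=NNC=C
C=CCCC=CN
C=NCN(C)SC
CC(C)CCO
CCC[C@H](C)F
CN=C(N)NSC
CN=CN=C(C)C
CN=CN[SH](=O)=O
CNC(=O)NCO
CNccccN
C[C@@H](F)CN
NCCC=CC=O
C=CC=C(C)OP
C=CC=NNCC
C=CCC=CN=C
C=CN(C)C(N)=O
CC(O)=CC=CN
CCN(C)C(N)=O
CCOCC(C)C
CS(=O)NC(=N)N
N=C(N)N[SH](=O)=O
O=CNC=O
C=C(O)C=CCN
C=CC(=N)C=C
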