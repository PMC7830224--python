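# 72-gene pain NGS panel: gene symbol, subsets the gene belongs to
# subset1: 29 key genes from the computational functional-genomics reduction
# subset2: 50 genes from the intersection of two independent proposals
gene_symbol	subsets
ADRA2A	subset1
ADRB2	subset1,subset2
AGER	subset1
APOE	subset1,subset2
CCL21	subset1
CCL5	subset1
CCR2	subset1
CCR7	subset1
CD4	subset1
CD40	subset1
CD74	subset1
CHRNA7	subset1
DRD1	subset1
DRD2	subset1,subset2
EDN1	subset1
F2R	subset1
F2RL1	subset1
IFNG	subset1
IL1B	subset1,subset2
IL6	subset1
LYN	subset1
MAPK1	subset1
OPRM1	subset1,subset2
P2RX7	subset1,subset2
PRKCA	subset1
PRKCD	subset1
TLR4	subset1
TLR9	subset1
TNF	subset1,subset2
ACAN	subset2
ACE	subset2
ADRA1D	subset2
ADRA2C	subset2
AR	subset2
CALCA	subset2
CASP9	subset2
CFTR	subset2
CRHBP	subset2
COMT	subset2
DRD4	subset2
ESR1	subset2
GCH1	subset2
GDF5	subset2
GSTM1	subset2
HLA-DRB1	subset2
HTR2A	subset2
IL1A	subset2
IL10	subset2
IL1RN	subset2
CXCL8	subset2
KCNS1	subset2
MAOA	subset2
MC2R	subset2
MTHFD1	subset2
MTRR	subset2
NFKBIA	subset2
NR3C1	subset2
PGR	subset2
POMC	subset2
PRSS1	subset2
PTGS2	subset2
SCN9A	subset2
SERPINA6	subset2
SHMT1	subset2
SMAD3	subset2
SOD2	subset2
SPINK1	subset2
STAT6	subset2
TGFB1	subset2
TRPA1	subset2
TRPM8	subset2
TRPV1	subset2
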