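gene_symbol	division	category
FN1	Core matrisome	ECM glycoproteins
TNC	Core matrisome	ECM glycoproteins
POSTN	Core matrisome	ECM glycoproteins
TGFBI	Core matrisome	ECM glycoproteins
LTBP1	Core matrisome	ECM glycoproteins
LTBP2	Core matrisome	ECM glycoproteins
FBN1	Core matrisome	ECM glycoproteins
FBN2	Core matrisome	ECM glycoproteins
FBLN2	Core matrisome	ECM glycoproteins
FBLN5	Core matrisome	ECM glycoproteins
MFAP2	Core matrisome	ECM glycoproteins
SRPX2	Core matrisome	ECM glycoproteins
ADAMTSL1	Core matrisome	ECM glycoproteins
THSD4	Core matrisome	ECM glycoproteins
DMBT1	Core matrisome	ECM glycoproteins
IGFBP4	Core matrisome	ECM glycoproteins
IGSF10	Core matrisome	ECM glycoproteins
THBS1	Core matrisome	ECM glycoproteins
THBS3	Core matrisome	ECM glycoproteins
ELN	Core matrisome	ECM glycoproteins
EMILIN1	Core matrisome	ECM glycoproteins
NID1	Core matrisome	ECM glycoproteins
LAMA1	Core matrisome	ECM glycoproteins
LAMB1	Core matrisome	ECM glycoproteins
LAMC1	Core matrisome	ECM glycoproteins
VTN	Core matrisome	ECM glycoproteins
SPARC	Core matrisome	ECM glycoproteins
DPT	Core matrisome	ECM glycoproteins
COL1A1	Core matrisome	Collagens
COL1A2	Core matrisome	Collagens
COL2A1	Core matrisome	Collagens
COL3A1	Core matrisome	Collagens
COL4A1	Core matrisome	Collagens
COL5A1	Core matrisome	Collagens
COL6A1	Core matrisome	Collagens
COL8A1	Core matrisome	Collagens
COL8A2	Core matrisome	Collagens
COL12A1	Core matrisome	Collagens
COL14A1	Core matrisome	Collagens
COL15A1	Core matrisome	Collagens
AGRN	Core matrisome	Proteoglycans
HSPG2	Core matrisome	Proteoglycans
DCN	Core matrisome	Proteoglycans
BGN	Core matrisome	Proteoglycans
LUM	Core matrisome	Proteoglycans
VCAN	Core matrisome	Proteoglycans
ACAN	Core matrisome	Proteoglycans
OGN	Core matrisome	Proteoglycans
PRELP	Core matrisome	Proteoglycans
ANXA1	Matrisome-associated	ECM-affiliated proteins
ANXA2	Matrisome-associated	ECM-affiliated proteins
ANXA5	Matrisome-associated	ECM-affiliated proteins
LGALS1	Matrisome-associated	ECM-affiliated proteins
LGALS3	Matrisome-associated	ECM-affiliated proteins
LMAN1	Matrisome-associated	ECM-affiliated proteins
C1QA	Matrisome-associated	ECM-affiliated proteins
C1QB	Matrisome-associated	ECM-affiliated proteins
C1QTNF5	Matrisome-associated	ECM-affiliated proteins
SEMA3A	Matrisome-associated	ECM-affiliated proteins
PLXNA1	Matrisome-associated	ECM-affiliated proteins
CLEC3B	Matrisome-associated	ECM-affiliated proteins
MMP2	Matrisome-associated	ECM regulators
MMP3	Matrisome-associated	ECM regulators
MMP9	Matrisome-associated	ECM regulators
TIMP1	Matrisome-associated	ECM regulators
TIMP2	Matrisome-associated	ECM regulators
TIMP3	Matrisome-associated	ECM regulators
LOX	Matrisome-associated	ECM regulators
LOXL1	Matrisome-associated	ECM regulators
LOXL2	Matrisome-associated	ECM regulators
P4HA1	Matrisome-associated	ECM regulators
P4HA2	Matrisome-associated	ECM regulators
PLOD1	Matrisome-associated	ECM regulators
CTSB	Matrisome-associated	ECM regulators
CTSK	Matrisome-associated	ECM regulators
SERPINC1	Matrisome-associated	ECM regulators
SERPINB2	Matrisome-associated	ECM regulators
SERPINE1	Matrisome-associated	ECM regulators
ITIH1	Matrisome-associated	ECM regulators
ITIH4	Matrisome-associated	ECM regulators
KNG1	Matrisome-associated	ECM regulators
PLAT	Matrisome-associated	ECM regulators
PLG	Matrisome-associated	ECM regulators
F2	Matrisome-associated	ECM regulators
A2M	Matrisome-associated	ECM regulators
CSTB	Matrisome-associated	ECM regulators
HTRA1	Matrisome-associated	ECM regulators
IL1RN	Matrisome-associated	Secreted factors
S100A4	Matrisome-associated	Secreted factors
S100A8	Matrisome-associated	Secreted factors
S100A9	Matrisome-associated	Secreted factors
S100A10	Matrisome-associated	Secreted factors
TGFB1	Matrisome-associated	Secreted factors
VEGFA	Matrisome-associated	Secreted factors
FGF2	Matrisome-associated	Secreted factors
CXCL12	Matrisome-associated	Secreted factors
WNT5A	Matrisome-associated	Secreted factors
ANGPTL4	Matrisome-associated	Secreted factors
CTGF	Matrisome-associated	Secreted factors
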