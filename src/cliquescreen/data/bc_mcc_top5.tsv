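gene	mcc_rank	is_biomarker
CCNA2	1	0
CCNB1	1	1
CDK1	1	0
CDC20	1	1
TTK	5	0
AURKA	5	1
TOP2A	5	0
MELK	8	1
CCNB2	8	0
BUB1	8	0
BIRC5	11	1
KIF2C	12	1
TPX2	12	0
BUB1B	12	1
KIF11	15	0
PRC1	15	1
NDC80	17	1
CEP55	18	1
RRM2	19	1
AURKB	19	0
HMMR	21	0
CDKN3	22	0
CENPA	23	1
MKI67	24	1
FOXM1	25	0
NEK2	26	1
CDC25C	27	0
UBE2C	28	1
PLK1	29	0
CENPF	30	1
CDCA2	31	0
EXO1	32	1
PTTG1	33	1
CDC6	34	1
CHEK1	35	0
TK1	36	0
GRB2	37	0
FGF4	38	0
FGF20	38	0
FGF6	38	0
FGF17	38	0
FGF9	38	0
FGF8	38	0
FGF5	38	0
FGF1	38	0
FGF22	38	0
FGF10	38	0
FGF7	38	0
FGF18	38	1
FGF19	38	0
FGF16	38	0
FGF3	38	0
FGF2	38	0
PTPN11	54	0
SHC1	55	0
PIK3R1	56	0
PIK3CA	56	0
ERBB2	58	1
PIK3CB	59	0
KRAS	60	0
NRAS	61	0
HRAS	61	0
FGFR4	63	1
FGFR3	63	0
FGFR2	63	0
FGFR1	63	0
EGFR	67	1
ERBB3	68	0
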