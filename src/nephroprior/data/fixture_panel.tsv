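version: fixture-2020.1
# Illustrative kidney-disease gene panel used for pipeline fixtures and
# synthetic cohorts.  NOT a clinically curated panel.
symbol	chromosome	modes	categories	digenic_partners	lof_mechanism
PKD1	16	AD	CILIOPATHY	.	true
PKD2	4	AD	CILIOPATHY	.	true
GANAB	11	AD	CILIOPATHY	.	true
DNAJB11	3	AD	CILIOPATHY	.	true
PKHD1	6	AR	CILIOPATHY	.	true
NPHP1	2	AR	CILIOPATHY	NPHP4	true
NPHP3	3	AR	CILIOPATHY	.	true
NPHP4	1	AR	CILIOPATHY	NPHP1	true
INVS	9	AR	CILIOPATHY	.	true
IQCB1	3	AR	CILIOPATHY	.	true
CEP290	12	AR	CILIOPATHY	.	true
TMEM67	8	AR	CILIOPATHY	.	true
ANKS6	9	AR	CILIOPATHY	.	true
IFT140	16	AR	CILIOPATHY	.	true
BBS1	11	AR	CILIOPATHY	.	true
BBS2	16	AR	CILIOPATHY	.	true
BBS10	12	AR	CILIOPATHY	.	true
ALMS1	2	AR	CILIOPATHY	.	true
OFD1	X	XL	CILIOPATHY	.	true
HNF1B	17	AD	CAKUT,CILIOPATHY,TUBULAR	.	true
PAX2	10	AD	CAKUT,GLOMERULAR	.	true
EYA1	8	AD	CAKUT	.	true
SIX1	14	AD	CAKUT	.	true
SALL1	16	AD	CAKUT	.	true
GATA3	10	AD	CAKUT	.	true
ANOS1	X	XL	CAKUT	.	true
RET	10	AD	CAKUT	.	true
ROBO2	3	AD	CAKUT	.	true
SOX17	8	AD	CAKUT	.	true
UPK3A	22	AD	CAKUT	.	true
DSTYK	1	AD	CAKUT	.	true
CHD7	8	AD	CAKUT	.	true
GREB1L	18	AD	CAKUT	.	true
TBX18	6	AD	CAKUT	.	true
PAX8	2	AD	CAKUT	.	true
NRIP1	21	AD	CAKUT	.	true
TNXB	6	AD	CAKUT	.	true
COL4A3	2	AD_AR	GLOMERULAR	.	true
COL4A4	2	AD_AR	GLOMERULAR	.	true
COL4A5	X	XL	GLOMERULAR	.	true
NPHS1	19	AR	GLOMERULAR	.	true
NPHS2	1	AR	GLOMERULAR	.	true
WT1	11	AD	GLOMERULAR	.	true
INF2	14	AD	GLOMERULAR	.	true
TRPC6	11	AD	GLOMERULAR	.	true
ACTN4	19	AD	GLOMERULAR	.	true
CD2AP	6	AD_AR	GLOMERULAR	.	true
LMX1B	9	AD	GLOMERULAR	.	true
SMARCAL1	2	AR	GLOMERULAR	.	true
LAMB2	3	AR	GLOMERULAR	.	true
PLCE1	10	AR	GLOMERULAR	.	true
MYO1E	15	AR	GLOMERULAR	.	true
CUBN	10	AR	GLOMERULAR	.	true
PTPRO	12	AR	GLOMERULAR	.	true
MYH9	22	AD	GLOMERULAR	.	true
FN1	2	AD	GLOMERULAR	.	true
COL4A1	13	AD	GLOMERULAR	.	true
CFH	1	AD_AR	HUS	CD46	true
CFI	4	AD	HUS	.	true
CFB	6	AD	HUS	.	true
CD46	1	AD_AR	HUS	CFH	true
C3	19	AD	HUS	.	true
THBD	20	AD	HUS	.	true
DGKE	17	AR	HUS	.	true
SLC3A1	2	AR	NEPHROLITHIASIS_NEPHROCALCINOSIS	.	true
SLC7A9	19	AD_AR	NEPHROLITHIASIS_NEPHROCALCINOSIS	.	true
AGXT	2	AR	NEPHROLITHIASIS_NEPHROCALCINOSIS	.	true
GRHPR	9	AR	NEPHROLITHIASIS_NEPHROCALCINOSIS	.	true
HOGA1	10	AR	NEPHROLITHIASIS_NEPHROCALCINOSIS	.	true
CYP24A1	20	AR	NEPHROLITHIASIS_NEPHROCALCINOSIS	.	true
SLC34A1	5	AD_AR	NEPHROLITHIASIS_NEPHROCALCINOSIS,TUBULAR	.	true
CLDN16	3	AR	TUBULAR,NEPHROLITHIASIS_NEPHROCALCINOSIS	.	true
CLDN19	1	AR	TUBULAR,NEPHROLITHIASIS_NEPHROCALCINOSIS	.	true
UMOD	16	AD	TUBULAR	.	true
REN	1	AD	TUBULAR	.	true
SEC61A1	3	AD	TUBULAR	.	true
HNF4A	20	AD	TUBULAR	.	true
SLC12A1	15	AR	TUBULAR	.	true
SLC12A3	16	AR	TUBULAR	.	true
KCNJ1	11	AR	TUBULAR	.	true
BSND	1	AR	TUBULAR	.	true
CLCNKB	1	AR	TUBULAR	.	true
CASR	3	AD_AR	TUBULAR	.	true
CTNS	17	AR	TUBULAR	.	true
OCRL	X	XL	TUBULAR	.	true
CLCN5	X	XL	TUBULAR,NEPHROLITHIASIS_NEPHROCALCINOSIS	.	true
AVPR2	X	XL	TUBULAR	.	true
AQP2	12	AD_AR	TUBULAR	.	true
ATP6V0A4	7	AR	TUBULAR	.	true
ATP6V1B1	2	AR	TUBULAR	.	true
SLC4A1	17	AD_AR	TUBULAR	.	true
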