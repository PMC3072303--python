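gene	alias	microarray_evidence	cell_type	cluster	metagene	algorithm_term
DDX18		3		1.1
SSRP1		3		1.2
CCT2		3	2	1.3
RPL28		N	2	1.4	Norm	2b
XIST		2	1,4,5	1.5
RASSF7		3		1.6
PKD1		3		1.7
AGPAT5		3	2,7	1.8
GLS		3		1.9
TMC8		3		1.10	1	3b,4b
RPS4Y1		2	3	1.11
KLF12		3	4	1.12
LCK		2,3	3,4,8	1.13
CD3D		2,3	3,4,8	1.14	1	3b,4b
AES		3		1.15
ZAP70		3	3,4,8	1.16
CD81		3	7,8	1.17
QDPR		3	2,5	1.18
FXN		2	2	1.19
CORO2A		3		1.20
TCEA1		3	7	1.21
KMO		3	5,7	2.1
TLR7		3	5	2.2
RHOC		3		2.3
CX3CR1		3	6,8	2.4
IL11RA		1,2	3,4	3.1
IL7R		1,2,3	3,4,8	3.2	3
FAIM3		2,3	3,4,7	3.3
TCF7		2,3	3,4,8	3.4	3
CD79B		2,3	7	3.5	2	4a
SPIB		2,3	2,5,7	3.6	2	4a
CD19		3	5,7	3.7
BLK		3	5,7	3.8
PI16		2		3.9
LRRN3		3	3,4	3.10	4
HNRNPF		N		4.1	Norm	5b,6b
TFCP2		N		4.2	Norm	5b,6b
ACBD5		3		4.3
DIAPH1		3		4.4
CD37		3	7	4.5
PLAGL2		3	1	4.6
SRA1		3		5.1
CD300A		2	8	5.2
ELMO2		3	5,8	5.3
CD33		2	1,6	6.1
CSPG2		1,2		6.2
CAT		2	2,5	6.3
NOD2		1,3	1,6	6.4
KCNMB1		2		6.5	5
TCF7L2		3	1,6,8	6.6	5
PDK4		3		6.7	5
TBC1D8		3	1,5,6	6.8
NR4A1		3	5	7.1
CDKN1C		3	6,8	7.2
C2		2		7.3
CLC		2	1,2	8.1	6
OLIG2		2		8.2
ADORA3		2		8.3	6
MMD		1,2,3	7	9.1
HIST1H2AE		1,3	4,7	9.2	7
AMFR		2		10.1
CD34		N	2	10.2
A_24_P128361	AF289562	3		11.1	8	5a
CD248		2,3	4	11.2
KLRC4		2	4,8	12.1	9	3a
TARP		2,3	4,8	12.2
CCR5		2	4,5	12.3
CD8A		1	3,4,8	12.4
SLAMF7		2	5,8	12.5	9	3a
KLRC2		2	3,4,8	12.6
PRSS23		2	8	12.7
NCAM1		N	8	12.8
TNFRSF10C		3		13.1	11	1b
IL8RB		1,3	1,6,8	13.2	11	1b
TLR4		3	1,6	13.3	11	1b
NAMPT		3	1,5,6	13.4
AQP9		3	1,6	13.5	10	2c
S100A8		1,2,3	1,5,6	13.6	12	2a
NCF4		2,3	1,6	13.7	10	2c
GLT1D1		1,2,3		13.8
TXN		2,3	2,5	13.9
GABARAPL1		3		13.10
SIRPB2		1,3		13.11
TRPM6		3		13.12
CD93		1,2,3	1,5,6	13.13
ASPRV1		3		13.14
ALOX5AP		2,3	5	13.15
BCL2A1		1,2,3	1,6,8	13.16
F11R		3		14.1
PTAFR		3	1,6	14.2
H3F3B		3	7	14.3
TYROBP		2,3	1,6,8	14.4
NCF2		3	1,5,6	14.5
KCNE3		2,3	1,6	14.6	11	1b
LAMP2		2,3	1	14.7
PLAUR		3	1,6	14.8
CD14		1	1,5,6	14.9
HK3		1,2	1,6,8	14.10
IL18		1		14.11
RGS18		1,2	1,6	15.1
BMX		2,3		16.1
MMP9		2,3		16.2
S100A12		1,2,3	1,5,6	16.3	12	2a
CLEC4E		2,3		16.4	12	2a
CLEC4D		2,3	1,6	16.5
CASP5		2,3		16.6	13	1a
TNFAIP6		2,3	1	16.7	13	1a
IL18RAP		1,3	3,4,8	16.8	13	1a
ARG1		2,3		17.1	14
HP		1	1,2	17.2
CBS		2,3		17.3	14
AF161365	TSPAN16	3		17.4	15	6a
ALAS2		CN		18.1
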