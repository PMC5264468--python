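gene	clone	xa_reads	xi_reads	total_reads	xi_pct	tau_i0
ARSD	12	238	236	474	49.8	0
ARSD	34	284	14	298	4.7	1.52e-06
CA5B	12	298	133	431	30.9	0
CA5B	34	255	42	297	14.1	0
CDK16	12	4232	525	4757	11.0	0
CDK16	34	3647	428	4075	10.5	0
CENPI	12	167	6	173	3.5	0.0113
CENPI	34	114	8	122	6.6	1.11e-05
CXorf40A	12	1341	3	1344	0.2	0.9975
CXorf40A	34	726	191	917	20.8	0
GEMIN8	12	61	46	107	43.0	0
GEMIN8	34	83	25	108	23.1	0
GYG2	12	73	31	104	29.8	0
GYG2	34	27	0	27	0.0	0.9834
HCCS	12	23	71	94	75.5	0
HCCS	34	221	0	221	0.0	0.9951
MED14	12	441	34	475	7.2	0
MED14	34	268	15	283	5.3	1.73e-07
MXRA5	12	9706	97	9803	1.0	0.0194
MXRA5	34	6020	827	6847	12.1	0
PLCXD1	12	34	22	56	39.3	0
PLCXD1	34	16	35	51	68.6	0
PNPLA4	12	106	19	125	15.2	0
PNPLA4	34	108	2	110	1.8	0.6737
PRKX	12	298	2	300	0.7	0.9898
PRKX	34	62	6	68	8.8	2.04e-05
RIBC1	12	18	6	24	25.0	1.73e-08
RIBC1	34	22	0	22	0.0	0.9812
RP11-1148L6.5	12	835	0	835	0.0	0.9998
RP11-1148L6.5	34	137	5	142	3.5	0.0153
RP11-706O15.1	12	564	24	588	4.1	2.18e-08
RP11-706O15.1	34	392	5	397	1.3	0.5506
SYAP1	12	45	16	61	26.2	0
SYAP1	34	44	6	50	12.0	6.16e-06
TMSB4X	12	31358	660	32018	2.1	4.15e-06
TMSB4X	34	32145	9	32154	0.0	0.9873
UXT	12	48	26	74	35.1	0
UXT	34	30	33	63	52.4	0
WASH6P	12	13	11	24	45.8	0
WASH6P	34	12	10	22	45.5	0
XG	12	4868	4337	9205	47.1	0
XG	34	3878	561	4439	12.6	0
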