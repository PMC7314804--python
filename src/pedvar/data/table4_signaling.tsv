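target	phospho_site	control_intensity	control_error_pct	treatment_intensity	treatment_error_pct	printed_cfc
STAT2	Y690	12.07	25.00	3998.24	30.54	3020.71
CTNNB1	Pan-specific	8899.32	36.86	39376.07	34.98	342.46
ABL1	Pan-specific	370.84	1.81	1007.12	69.04	171.57
CDK2	T160	4985.72	4.41	13344.65	89.59	167.66
CDK1	T14	994.27	14.90	2458.99	97.52	147.32
CAV2	Pan-specific	2203.31	14.29	4762.67	31.30	116.16
MKK4	Pan-specific	1560.23	13.09	3060.01	8.75	96.13
BRSK1	T189	2885.11	30.13	5491.48	25.83	90.34
BCK2L7	Pan-specific	581.21	6.27	1025.35	18.75	76.42
MAP3K7	S439	2880.44	11.14	5061.08	54.95	75.70
SIT	Y90	3956.22	13.01	6810.59	16.99	72.15
CCNE1	T395	12311.81	20.41	20821.20	19.41	69.12
CHK1	S280	6169.84	13.46	10126.81	0.50	64.13
CTNNB1	S33	17747.78	3.23	29076.53	7.81	63.83
CDK7	Pan-specific	5430.82	19.64	8884.29	6.89	63.59
BLK	Y188	1865.68	7.41	3028.97	14.49	62.35
CHK1	S317	2336.62	11.57	3734.82	23.01	59.84
WNK1	T2245	1205.36	47.18	481.67	0.24	-60.04
p53	Pan-specific	1547.83	26.94	602.34	18.41	-61.09
MDM2	S166	11394.35	5.37	4330.00	10.92	-62.00
p70 S6K	Pan-specific	1047.28	7.61	292.15	1.45	-72.10
PDGFRa	Y754	1927.40	21.94	527.39	17.82	-72.64
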