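# Synthetic reconstruction of the 28-member UBRS033-style family:
# per-individual structure is invented but consistent with every published
# count (8 affected incl. the III:3/III:4 twin pair, 20 unaffected, 16 typed,
# married-in affected spouses II:11 and II:12, deceased founder I:1).
# Columns: family individual father mother sex phenotype age mz_twin_group
UBRS033	I:1	0	0	1	0	.	.
UBRS033	I:2	0	0	2	1	78	.
UBRS033	II:1	I:1	I:2	2	2	59	.
UBRS033	II:3	I:1	I:2	1	2	54	.
UBRS033	II:4	I:1	I:2	2	2	52	.
UBRS033	II:5	I:1	I:2	1	2	48	.
UBRS033	II:6	I:1	I:2	1	1	47	.
UBRS033	II:7	I:1	I:2	1	1	44	.
UBRS033	II:8	0	0	2	1	50	.
UBRS033	II:9	0	0	1	1	54	.
UBRS033	II:10	0	0	2	1	45	.
UBRS033	II:11	0	0	1	2	63	.
UBRS033	II:12	0	0	2	2	48	.
UBRS033	II:13	0	0	2	1	42	.
UBRS033	III:1	II:11	II:1	2	1	38	.
UBRS033	III:2	II:11	II:1	1	1	36	.
UBRS033	III:3	II:3	II:8	2	2	34	TW1
UBRS033	III:4	II:3	II:8	2	2	34	TW1
UBRS033	III:5	II:3	II:8	2	1	29	.
UBRS033	III:6	II:5	II:12	1	1	22	.
UBRS033	III:7	II:9	II:4	2	1	20	.
UBRS033	III:8	II:9	II:4	1	1	26	.
UBRS033	III:9	II:5	II:12	2	1	18	.
UBRS033	III:10	II:6	II:10	1	1	24	.
UBRS033	III:11	II:6	II:10	2	1	21	.
UBRS033	III:12	II:7	II:13	1	1	19	.
UBRS033	III:13	II:7	II:13	2	1	16	.
UBRS033	III:14	II:7	II:13	1	1	14	.
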