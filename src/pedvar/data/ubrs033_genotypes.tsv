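# Synthetic genotype reconstruction for the 16 typed members of the
# UBRS033-style pedigree: alternate-allele counts for the three variants that
# were followed up by segregation analysis.  The pattern reproduces every
# published statement (PBK heterozygous in the six affected descendants and
# the 22-year-old unaffected III:6, absent elsewhere; ANKRD36 and SORL1
# shared by the five sequenced affecteds but discordant in the wider family).
individual_id	variant_id	call
I:2	PBK_c127GA	0
II:1	PBK_c127GA	1
II:3	PBK_c127GA	1
II:4	PBK_c127GA	1
II:5	PBK_c127GA	1
II:6	PBK_c127GA	0
II:7	PBK_c127GA	0
II:11	PBK_c127GA	0
II:12	PBK_c127GA	0
II:13	PBK_c127GA	0
III:1	PBK_c127GA	0
III:3	PBK_c127GA	1
III:4	PBK_c127GA	1
III:5	PBK_c127GA	0
III:6	PBK_c127GA	1
III:7	PBK_c127GA	0
I:2	ANKRD36_c202GA	0
II:1	ANKRD36_c202GA	1
II:3	ANKRD36_c202GA	1
II:4	ANKRD36_c202GA	1
II:5	ANKRD36_c202GA	0
II:6	ANKRD36_c202GA	0
II:7	ANKRD36_c202GA	0
II:11	ANKRD36_c202GA	0
II:12	ANKRD36_c202GA	0
II:13	ANKRD36_c202GA	0
III:1	ANKRD36_c202GA	0
III:3	ANKRD36_c202GA	1
III:4	ANKRD36_c202GA	1
III:5	ANKRD36_c202GA	1
III:6	ANKRD36_c202GA	0
III:7	ANKRD36_c202GA	0
I:2	SORL1_c4501CT	0
II:1	SORL1_c4501CT	1
II:3	SORL1_c4501CT	1
II:4	SORL1_c4501CT	1
II:5	SORL1_c4501CT	1
II:6	SORL1_c4501CT	0
II:7	SORL1_c4501CT	0
II:11	SORL1_c4501CT	0
II:12	SORL1_c4501CT	0
II:13	SORL1_c4501CT	0
III:1	SORL1_c4501CT	1
III:3	SORL1_c4501CT	1
III:4	SORL1_c4501CT	1
III:5	SORL1_c4501CT	0
III:6	SORL1_c4501CT	0
III:7	SORL1_c4501CT	0
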