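# 17 candidate variants surviving the family-exome filter cascade, with the
# damaging/benign verdicts of six external effect predictors.  Frequencies are
# 1000 Genomes allele frequencies; '.' marks a novel variant with no entry.
# The per-tool verdict strings are a synthetic assignment that reproduces the
# published per-variant damaging-verdict counts (only the counts were printed).
chrom	pos	gene	dbsnp	af_1000g	effect	hgvs_c	hgvs_p	polyphen2	variowatch	mutationtaster	sift	mutation_assessor	lrt
2	97783805	ANKRD36	rs571299992	0.00199681	Missense variant	c.202G>A	p.Ala68Thr	Probably damaging	Deleterious	Disease causing	Damaging	Damaging	Neutral
8	27685647	PBK	.	.	Missense variant	c.127G>A	p.Gly43Arg	Probably damaging	Deleterious	Disease causing	Damaging	Damaging	Neutral
1	85028969	CTBS	rs3768249	0.0091853	Missense variant	c.928G>T	p.Asp310Tyr	Possibly damaging	Deleterious	Disease causing	Tolerated	Neutral	Neutral
12	77427693	E2F7	rs139349075	0.00159744	Missense variant	c.1253A>G	p.Glu418Gly	Possibly damaging	Deleterious	Disease causing	Tolerated	Neutral	Neutral
15	6769914	FNDC9	rs201701167	0.000399361	Missense variant	c.631G>T	p.Gly211Trp	Possibly damaging	Deleterious	Disease causing	Tolerated	Neutral	Neutral
12	10588530	KLRC2	rs75545535	.	Missense variant	c.56G>C	p.Arg19Pro	Possibly damaging	Deleterious	Disease causing	Tolerated	Neutral	Neutral
12	110944398	RAD9B	rs552692137	0.000599042	Missense variant	c.288C>G	p.Ile96Met	Possibly damaging	Deleterious	Disease causing	Tolerated	Neutral	Neutral
11	121466463	SORL1	.	.	Missense variant	c.4501C>T	p.Arg1501Trp	Possibly damaging	Deleterious	Disease causing	Tolerated	Neutral	Neutral
8	30701641	TEX15	rs142485241	0.00638978	Missense variant	c.4893G>C	p.Gln1631His	Possibly damaging	Deleterious	Disease causing	Tolerated	Neutral	Neutral
2	98525148	TMEM131	rs535701294	0.00179712	Missense variant	c.263T>C	p.Leu88Pro	Possibly damaging	Deleterious	Disease causing	Tolerated	Neutral	Neutral
22	20761028	ZNF74	rs190749586	0.000998403	Missense variant	c.1705T>C	p.Ser569Pro	Possibly damaging	Deleterious	Disease causing	Tolerated	Neutral	Neutral
9	34725069	FAM205A	rs114933270	.	Missense variant	c.2168A>T	p.Glu723Val	Possibly damaging	Deleterious	Polymorphism	Tolerated	Neutral	Neutral
12	15035203	MGP	rs374434209	.	Missense variant	c.257G>A	p.Arg86His	Possibly damaging	Deleterious	Polymorphism	Tolerated	Neutral	Neutral
18	77895740	ADNP2	rs113879497	0.00359425	Missense variant	c.2444A>G	p.Asn815Ser	Benign	Deleterious	Polymorphism	Tolerated	Neutral	Neutral
5	140229086	PCDHA9	rs251354	.	Missense variant	c.1006C>G	p.Leu336Val	Benign	Deleterious	Polymorphism	Tolerated	Neutral	Neutral
2	103149147	SLC9A4	rs79918239	0.00179712	Stop retained variant	c.2397G>A	p.Ter799=	Benign	Deleterious	Polymorphism	Tolerated	Neutral	Neutral
12	123810152	SBNO1	rs373314152	0.000199681	Splice region variant & intron variant	c.1876-6C>T	.	Benign	Neutral	Polymorphism	Tolerated	Neutral	Neutral
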