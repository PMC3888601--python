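# Novel RYR2 missense variants from a CPVT cohort (155 patients) with their
# paralogue annotations.  gene/protein_hgvs columns describe the paralogue
# disease variant; query_* columns the annotated RYR2 variant.
query_gene	cds_hgvs	query_hgvs	region	cases	exon	gene	protein_hgvs	disease	consensus	pmid
RYR2	c.527G>A	p.R176Q	N-terminal hotspot	1	8	RYR1	R163L	Malignant hyperthermia	9
RYR2	c.527G>A	p.R176Q	N-terminal hotspot	1	8	RYR1	R163C	Central core disease	9
RYR2	c.994C>T	p.R332W	N-terminal hotspot	1	12	RYR1	R316L	Malignant hyperthermia	8
RYR2	c.1069G>A	p.G357S	N-terminal hotspot	1	13	RYR1	G341R	Malignant hyperthermia	9
RYR2	c.1069G>A	p.G357S	N-terminal hotspot	1	13	RYR1	G341R	Malignant hyperthermia	9
RYR2	c.1646C>T	p.A549V	Outside hotspots	1	17	RYR1	A537T	Congenital myopathy	9
RYR2	c.6504C>G	p.H2168Q	Outside hotspots	2	42	RYR1	H2204Q	Multiminicore disease	9
RYR2	c.7258A>T	p.R2420W	Central hotspot	1	48	RYR1	R2454C	Malignant hyperthermia	9
RYR2	c.7258A>T	p.R2420W	Central hotspot	1	48	RYR1	R2454H	Malignant hyperthermia	9
RYR2	c.11989A>G	p.K3997E	Channel hotspot	1	90	RYR1	R4041W	Malignant hyperthermia	9
RYR2	c.14369G>A	p.R4790Q	Channel hotspot	1	100	RYR1	R4861C	Central core disease	9
RYR2	c.14369G>A	p.R4790Q	Channel hotspot	1	100	RYR1	R4861H	Central core disease	9
RYR2	c.14414A>G	p.K4805R	Channel hotspot	1	100	RYR1	K4876R	Malignant hyperthermia	9
RYR2	c.14465G>A	p.R4822H	Channel hotspot	1	101	RYR1	R4893W	Central core disease	9
RYR2	c.14465G>A	p.R4822H	Channel hotspot	1	101	RYR1	R4893Q	Central core disease	9
RYR2	c.14465G>A	p.R4822H	Channel hotspot	1	101	RYR1	R4893P	Central core disease	9
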