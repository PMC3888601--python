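# Novel SCN5A missense variants from a BrS cohort (2111 patients) with their
# paralogue annotations.  gene/protein_hgvs columns describe the paralogue
# disease variant; query_* columns the annotated SCN5A variant.
query_gene	cds_hgvs	query_hgvs	region	cases	exon	gene	protein_hgvs	disease	consensus	pmid
SCN5A	c.278T>C	p.F93S	N-terminus	1	3	SCN1A	F90S	Myoclonic epilepsy of infancy	5
SCN5A	c.281T>G	p.I94S	N-terminus	1	3	SCN1A	I91T	Myoclonic epilepsy of infancy	5
SCN5A	c.362G>A	p.R121Q	N-terminus	2	3	SCN1A	R118S	Myoclonic epilepsy of infancy	9
SCN5A	c.533C>G	p.A178G	TM domain 1	1	5	SCN1A	A175V	Dravet syndrome	9
SCN5A	c.533C>G	p.A178G	TM domain 1	1	5	SCN1A	A175T	Myoclonic epilepsy of infancy	9
SCN5A	c.659C>T	p.T220I	TM domain 1	2	6	SCN1A	T217K	Myoclonic epilepsy of infancy	9
SCN5A	c.694G>A	p.V232I	TM domain 1	2	6	CACNA1H	R212R	Autism spectrum disorder	9
SCN5A	c.1100G>T	p.R367L	TM domain 1	1	9	SCN1A	R377Q	Generalised epilepsy with febrile seizures	9
SCN5A	c.1100G>T	p.R367L	TM domain 1	1	9	SCN1A	R377L	Dravet syndrome	9
SCN5A	c.1120T>G	p.W374G	TM domain 1	1	9	SCN1A	W384R	Dravet syndrome	9
SCN5A	c.1120T>G	p.W374G	TM domain 1	1	9	SCN1A	W384X	Myoclonic epilepsy of infancy	9
SCN5A	c.1157G>A	p.G386E	TM domain 1	2	10	SCN1A	G396E	Dravet syndrome	8
SCN5A	c.1156G>A	p.G386R	TM domain 1	1	10	SCN1A	G396E	Dravet syndrome	8
SCN5A	c.1187T>C	p.V396A	TM domain 1	1	10	SCN1A	V406F	Dravet syndrome	9
SCN5A	c.1186G>C	p.V396L	TM domain 1	1	10	SCN1A	V406F	Dravet syndrome	9
SCN5A	c.2047T>G	p.C683G	Interdomain Linker I-II	1	14	SCN9A	C699Y	Dravet syndrome	3
SCN5A	c.2047T>G	p.C683G	Interdomain Linker I-II	1	14	CACNA1H	R744Q	Childhood absence epilepsy	3
SCN5A	c.2150C>T	p.P717L	TM domain 2	1	14	SCN1A	P768L	Myoclonic epilepsy of infancy	8
SCN5A	c.2553C>A	p.F851L	TM domain 2	1	16	SCN1A	F902C	Myoclonic epilepsy of infancy	9
SCN5A	c.2633G>A	p.R878H	TM domain 2	5	16	SCN1A	R931C	Myoclonic epilepsy of infancy	8
SCN5A	c.2633G>A	p.R878H	TM domain 2	5	16	SCN9A	R896Q	Congenital indifference to pain	8
SCN5A	c.2633G>A	p.R878H	TM domain 2	5	16	SCN1A	R931H	Epilepsy	8
SCN5A	c.2657A>C	p.H886P	TM domain 2	1	16	SCN1A	H939Q	Myoclonic epilepsy of infancy	9
SCN5A	c.2657A>C	p.H886P	TM domain 2	1	16	SCN1A	H939Y	Dravet syndrome	9
SCN5A	c.2657A>C	p.H886P	TM domain 2	1	16	CACNA1H	W962C	Autism spectrum disorder	9
SCN5A	c.2677C>T	p.R893C	TM domain 2	2	16	SCN1A	R946S	Generalised epilepsy of infancy	9
SCN5A	c.2677C>T	p.R893C	TM domain 2	2	16	SCN1A	R946C	Myoclonic epilepsy of infancy	9
SCN5A	c.2677C>T	p.R893C	TM domain 2	2	16	SCN1A	R946H	Myoclonic epilepsy of infancy	9
SCN5A	c.2678G>A	p.R893H	TM domain 2	3	16	SCN1A	R946S	Generalised epilepsy of infancy	9
SCN5A	c.2678G>A	p.R893H	TM domain 2	3	16	SCN1A	R946C	Myoclonic epilepsy of infancy	9
SCN5A	c.2678G>A	p.R893H	TM domain 2	3	16	SCN1A	R946H	Myoclonic epilepsy of infancy	9
SCN5A	c.2701G>A	p.E901K	TM domain 2	3	16	SCN1A	E954K	Dravet syndrome	9
SCN5A	c.3695G>A	p.R1232Q	TM domain 3	1	21	SCN1A	R1245Q	Myoclonic epilepsy of infancy	7
SCN5A	c.3758A>G	p.E1253G	TM domain 3	1	21	SCN1A	E1266A	Dravet syndrome	9
SCN5A	c.3813G>C	p.W1271C	TM domain 3	1	21	SCN1A	W1284S	Dravet syndrome	9
SCN5A	c.3968T>G	p.V1323G	TM domain 3	1	23	SCN9A	V1299F	Paroxysmal extreme pain disorder	9
SCN5A	c.4057G>A	p.V1353M	TM domain 3	2	23	SCN1A	V1366I	Generalised epilepsy with febrile seizures	9
SCN5A	c.4079T>G	p.F1360C	TM domain 3	1	23	CACNA1A	F1404C	Episodic ataxia	9
SCN5A	c.4226A>G	p.Y1409C	TM domain 3	1	23	SCN1A	Y1422C	Myoclonic epilepsy of infancy	9
SCN5A	c.4234C>T	p.L1412F	TM domain 3	1	23	CACNA1F	L1079P	Night blindness	9
SCN5A	c.4255A>G	p.K1419E	TM domain 3	1	24	CACNA1C	E1115K	BrS	9
SCN5A	c.4258G>C	p.G1420R	TM domain 3	1	24	SCN1A	G1433R	Dravet syndrome	9
SCN5A	c.4258G>C	p.G1420R	TM domain 3	1	24	SCN1A	G1433E	Myoclonic epilepsy of infancy	9
SCN5A	c.4258G>C	p.G1420R	TM domain 3	1	24	SCN1A	G1433V	Dravet syndrome	9
SCN5A	c.4283C>T	p.A1428V	TM domain 3	1	24	SCN1A	A1441P	Myoclonic epilepsy of infancy	9
SCN5A	c.4321G>C	p.E1441Q	TM domain 3	1	25	CACNA1A	G1483R	Episodic ataxia	9
SCN5A	c.4321G>C	p.E1441Q	TM domain 3	1	25	SCN1A	E1454K	Dravet syndrome	9
SCN5A	c.4342A>C	p.I1448L	TM domain 3	1	25	SCN1A	L1461I	Myoclonic epilepsy of infancy	9
SCN5A	c.4343T>C	p.I1448T	TM domain 3	1	25	SCN1A	L1461I	Myoclonic epilepsy of infancy	9
SCN5A	c.4346A>G	p.Y1449C	TM domain 3	1	25	SCN1A	Y1462C	Myoclonic epilepsy of infancy	9
SCN5A	c.4346A>G	p.Y1449C	TM domain 3	1	25	CACNA1A	F1491S	Episodic ataxia	9
SCN5A	c.4346A>G	p.Y1449C	TM domain 3	1	25	SCN1A	Y1462H	Dravet syndrome	9
SCN5A	c.4387A>T	p.N1463Y	TM domain 3	1	25	SCN1A	N1476K	Dravet syndrome	9
SCN5A	c.4402G>T	p.V1468F	TM domain 3	1	25	SCN4A	V1293I	Paramyotonia congenita	9
SCN5A	c.4573G>A	p.V1525M	TM domain 4	1	27	SCN1A	V1538I	Dravet syndrome	9
SCN5A	c.4642G>A	p.E1548K	TM domain 4	3	27	SCN1A	E1561K	Dravet syndrome	9
SCN5A	c.4747C>T	p.R1583C	TM domain 4	2	27	SCN1A	R1596C	Cryptogenic focal epilepsy	9
SCN5A	c.4747C>T	p.R1583C	TM domain 4	2	27	SCN1A	R1596L	Dravet syndrome	9
SCN5A	c.4747C>T	p.R1583C	TM domain 4	2	27	SCN1A	R1596H	Generalised epilepsy with febrile seizures	9
SCN5A	c.4748G>A	p.R1583H	TM domain 4	1	27	SCN1A	R1596C	Cryptogenic focal epilepsy	9
SCN5A	c.4748G>A	p.R1583H	TM domain 4	1	27	SCN1A	R1596L	Dravet syndrome	9
SCN5A	c.4748G>A	p.R1583H	TM domain 4	1	27	SCN1A	R1596H	Generalised epilepsy with febrile seizures	9
SCN5A	c.4981G>C	p.G1661R	TM domain 4	1	28	SCN1A	G1674R	Myoclonic epilepsy of infancy	9
SCN5A	c.4981G>A	p.G1661R	TM domain 4	2	28	SCN1A	G1674R	Myoclonic epilepsy of infancy	9
SCN5A	c.5015C>A	p.S1672Y	TM domain 4	2	28	SCN1A	A1685D	Myoclonic epilepsy of infancy	9
SCN5A	c.5015C>A	p.S1672Y	TM domain 4	2	28	SCN1A	A1685V	Febrile seizures	9
SCN5A	c.5134G>A	p.G1712S	TM domain 4	1	28	SCN1A	G1725C	Dravet syndrome	9
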