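# The 19 SCN5A paralogues used for annotation: voltage-gated sodium channels
# and the homologous voltage-gated calcium channels, with counts of distinct
# HGMD missense variants, distinct affected residues, and variants mapped to
# SCN5A, plus major associated diseases.
gene	hgmd_missense_variants	hgmd_missense_residues	scn5a_annotations	major_diseases
SCN1A	410	327	393	Epilepsy, Dravet syndrome, Hemiplegic migraine
SCN2A	26	26	24	Epilepsy, Neonatal-infantile seizures
SCN3A	1	1	1	Epilepsy
SCN4A	67	53	67	Hyperkalaemic periodic paralysis, myotonia, paramyotonia congenita, periodic paralysis
SCN7A	0	0	0
SCN8A	1	1	1	Infantile epileptic encephalopathy
SCN9A	53	50	45	Congenital indifference to pain, primary erythermalgia, paroxysmal extreme pain disorder, small fibre neuropathy
SCN10A	0	0	0
SCN11A	0	0	0
CACNA1A	63	61	54	Episodic ataxia 2, hemiplegic migraine
CACNA1B	0	0	0
CACNA1C	9	9	4	BrS, LQTS
CACNA1D	1	1	0
CACNA1E	1	1	0
CACNA1F	28	28	27	Night blindness
CACNA1G	2	2	0	Juvenile myoclonic epilepsy
CACNA1H	25	25	13	Epilepsy, autism spectrum disorder
CACNA1I	0	0	0
CACNA1S	13	8	13	Hypokalaemic periodic paralysis, malignant hyperthermia
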