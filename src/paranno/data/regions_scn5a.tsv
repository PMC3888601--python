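# SCN5A protein domains.  Transmembrane ranges follow UniProt Q14524; the
# N-terminus, interlinker and C-terminus ranges are their complements.
gene	label	start	end	group
SCN5A	N-terminus	1	126	n_terminus
SCN5A	TM domain 1	127	415	transmembrane
SCN5A	Interlinker I-II	416	711	interlinker
SCN5A	TM domain 2	712	939	transmembrane
SCN5A	Interlinker II-III	940	1200	interlinker
SCN5A	TM domain 3	1201	1470	transmembrane
SCN5A	Interlinker III-IV	1471	1523	interlinker
SCN5A	TM domain 4	1524	1772	transmembrane
SCN5A	C-terminus	1773	2016	c_terminus
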