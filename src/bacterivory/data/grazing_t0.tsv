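group	abundance_per_ml	vacuole_bacteria_per_cell	is_community
All HNF	5400	2.9	1
All Crypto	3380	3.1	0
CRY1 lineage	100	1.8	0
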