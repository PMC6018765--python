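strain_id	lineage	volume_um3	length_um	width_um	width_source	shape
PnC1	PnecC	0.057	0.88	0.35172	derived	small solenoid
PnC6	PnecC	0.049	0.58	0.40168	derived	short rod
Rim11	LimB	0.051	0.63	0.39320	derived	short rod
Rim47	LimC4	0.055	0.66	0.39894	derived	coccoid
T6-5	LimC	0.472	2.21	0.63867	derived	thin curved rod
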