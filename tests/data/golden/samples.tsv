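sample_id	screen_id	arm	compound	concentration	lane	timepoint
S1_control	S1	control			pooled	d8
S1_treated	S1	treated	cpd1		pooled	d8
S2_control	S2	control			pooled	d8
S2_treated	S2	treated	cpd2		pooled	d8
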