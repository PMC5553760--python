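trait	r_within	bias_within	r_between	bias_between
milk	0.635	0.862	0.160	0.762
fat	0.607	0.808	0.070	0.482
protein	0.602	0.775	0.098	0.622
mastitis	0.504	0.864	-0.058	-0.343
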