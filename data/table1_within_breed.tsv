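trait	go_id	r_gfblup	bias	delta_r	h2_feature	m_f
milk	GO:0042572	0.655	0.863	0.020	0.169	586
milk	GO:0034605	0.655	0.864	0.020	0.185	1517
milk	GO:0040018	0.650	0.863	0.015	0.116	914
milk	GO:0008285	0.650	0.865	0.015	0.209	4972
milk	GO:0032496	0.648	0.864	0.013	0.144	1579
fat	GO:0042572	0.648	0.804	0.041	0.257	586
fat	GO:0034605	0.645	0.804	0.038	0.291	1517
fat	GO:0040018	0.644	0.801	0.037	0.200	914
fat	GO:0007283	0.640	0.802	0.033	0.323	4273
fat	GO:0000724	0.639	0.802	0.032	0.352	1308
protein	GO:0042572	0.612	0.782	0.010	0.051	586
protein	GO:0030154	0.610	0.783	0.008	0.016	9840
protein	GO:0090502	0.609	0.782	0.007	0.011	735
protein	GO:0042742	0.608	0.782	0.006	0.010	1231
protein	GO:0050821	0.607	0.781	0.005	0.021	3162
mastitis	GO:0042104	0.513	0.873	0.009	0.006	331
mastitis	GO:0050729	0.513	0.872	0.009	0.007	626
mastitis	GO:0043066	0.512	0.871	0.008	0.047	8158
mastitis	GO:0032465	0.511	0.872	0.007	0.014	151
mastitis	GO:0006914	0.510	0.871	0.006	0.018	1753
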