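trait	go_id	r_gfblup	bias	delta_r	h2_feature	m_f
milk	GO:0040018	0.360	0.826	0.200	0.103	962
milk	GO:0042572	0.342	0.808	0.182	0.171	678
milk	GO:0034605	0.336	0.805	0.176	0.178	1621
milk	GO:0045944	0.331	0.805	0.171	0.190	11185
milk	GO:0032496	0.325	0.798	0.165	0.129	1702
fat	GO:0042572	0.246	0.680	0.176	0.262	678
fat	GO:0000122	0.238	0.642	0.168	0.348	8755
fat	GO:0032496	0.200	0.577	0.130	0.219	1702
fat	GO:0007283	0.176	0.538	0.106	0.313	4950
fat	GO:0034605	0.171	0.558	0.101	0.271	1621
protein	GO:0042742	0.232	0.767	0.134	0.010	1333
protein	GO:0042475	0.224	0.732	0.126	0.011	3244
protein	GO:0006665	0.197	0.721	0.099	0.011	805
protein	GO:0042572	0.178	0.699	0.080	0.010	678
protein	GO:0006810	0.168	0.693	0.070	0.040	6999
mastitis	GO:0043066	0.077	0.277	0.135	0.064	8831
mastitis	GO:0032496	0.067	0.176	0.125	0.020	1702
mastitis	GO:0032091	0.045	0.171	0.103	0.032	702
mastitis	GO:0043280	0.018	0.178	0.076	0.003	583
mastitis	GO:0071346	0.014	0.115	0.072	0.020	3494
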