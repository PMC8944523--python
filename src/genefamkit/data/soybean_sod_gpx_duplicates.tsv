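pair_a	pair_b	ka	ks	ka_ks	duplication_type	reported_time_mya	reported_selection
GsoSOD3.1	GsoSOD19.1	0.067	0.051	1.298	segmental	4.18	positive
GsoSOD4.1	GsoSOD6.1	0.022	0.034	0.656	segmental	2.79	purifying
GsoSOD10.2	GsoSOD20.2	0.027	0.085	0.311	segmental	6.97	purifying
GsoSOD2.1	GsoSOD10.1	0.048	0.062	0.773	segmental	5.08	purifying
GmaSOD11.1	GmaSOD12.1	0.034	0.015	2.182	segmental	1.23	positive
GmaSOD10.2	GmaSOD20.2	0.036	0.054	0.666	segmental	4.43	purifying
GmaSOD3.1	GmaSOD19.1	0.066	0.037	1.811	segmental	3.03	positive
GmaSOD4.1	GmaSOD6.1	0.025	0.031	0.807	segmental	2.54	purifying
GsoGPX5.2	GsoGPX8.3	0.018	0.090	0.197	segmental	7.38	purifying
GsoGPX5.1	GsoGPX8.1	0.005	0.075	0.069	segmental	6.15	purifying
GsoGPX2.1	GsoGPX10.1	0.017	0.136	0.128	segmental	11.15	purifying
GmaGPX8.1	GmaGPX5.1	0.021	0.020	1.051	segmental	1.64	positive
GmaGPX14.1	GmaGPX17.1	0.059	0.062	0.941	segmental	5.08	purifying
GmaGPX5.2	GmaGPX8.3	0.033	0.000	nan	segmental	0.00	purifying
GmaGPX2.1	GmaGPX10.1	0.050	0.019	2.637	segmental	1.56	positive
GmaGPX11.1	GmaGPX1.1	0.013	0.010	1.306	segmental	0.82	positive
GmaGPX3.1	GmaGPX19.1	0.061	0.063	0.970	segmental	5.16	neutral
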