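sample	JCM	HDPGMM	FLAME
Sa001	0.3045	0.2046	0.5143
Sa002	0.0339	0.1044	0.4300
Sa003	0.0694	0.0946	0.5931
Sa004	0.0659	0.0946	0.5459
Sa005	0.0089	0.1230	0.4440
Sa006	0.2947	0.0611	0.5987
Sa007	0.0208	0.0510	0.2584
Sa008	0.0683	0.0719	0.3719
Sa009	0.0249	0.1343	0.2417
Sa010	0.0121	0.3828	0.5413
Sa011	0.0236	0.4082	0.4792
Sa012	0.0096	0.1148	0.2456
Sa013	0.0326	0.3247	0.5947
Sa014	0.0062	0.2959	0.6000
Sa015	0.1283	0.4110	0.3927
Sa016	0.0361	0.4437	0.5372
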