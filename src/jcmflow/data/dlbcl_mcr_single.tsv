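sample	JCM	FLAME-I	flowClust-I	SWIFT-I	FLAME-P	flowClust-P	SWIFT-P
Sa001	0.3045	0.3039	0.3070	0.5368	0.1666	0.2187	0.3039
Sa002	0.0339	0.3394	0.0388	0.1526	0.2146	0.4096	0.3060
Sa003	0.0694	0.0753	0.0588	0.4500	0.1790	0.3194	0.2204
Sa004	0.0659	0.0687	0.0682	0.5506	0.1227	0.1661	0.3038
Sa005	0.0089	0.1631	0.1868	0.4521	0.1415	0.0752	0.1220
Sa006	0.2947	0.2670	0.1150	0.3612	0.0809	0.3773	0.1869
Sa007	0.0208	0.0211	0.0217	0.2580	0.0943	0.0569	0.0438
Sa008	0.0683	0.0678	0.0997	0.1911	0.0852	0.1045	0.3560
Sa009	0.0249	0.3191	0.0891	0.2508	0.0487	0.0302	0.0186
Sa010	0.0121	0.0575	0.0111	0.5353	0.0628	0.0471	0.0757
Sa011	0.0236	0.0248	0.0248	0.1627	0.0240	0.1660	0.1004
Sa012	0.0096	0.3919	0.4613	0.2170	0.0421	0.0299	0.0188
Sa013	0.0326	0.0324	0.0355	0.5936	0.0796	0.0500	0.0581
Sa014	0.0062	0.0065	0.0083	0.5612	0.0857	0.0159	0.0373
Sa015	0.1283	0.1274	0.1317	0.5896	0.1093	0.1077	0.0947
Sa016	0.0361	0.0554	0.1832	0.4502	0.0524	0.0535	0.0803
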