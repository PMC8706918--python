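no	group	genome	ssr_type	type	ssr_name	start	end	unit_sequence	repeat_count	gene
1	SSRGroup 16	WBPHHN	Potential SSR	PentaSSR	P0000047	15346	15355	AATAA	2	Intergenic
1	SSRGroup 16	WBPHYN	Potential SSR	PentaSSR	P0000047	15346	15355	AATAA	2	Intergenic
2	SSRGroup 34	WBPHHN	Normal SSR	MonoSSR	M0000009	10023	10032	T	10	Intergenic
2	SSRGroup 34	WBPHTA	Normal SSR	MonoSSR	M0000009	10023	10032	T	10	Intergenic
3	SSRGroup 75	WBPHHN	Potential SSR	PentaSSR	P0000023	10333	10342	TACAC	2	CYTB
3	SSRGroup 75	WBPHYN	Potential SSR	PentaSSR	P0000023	10333	10342	TACAC	2	CYTB
4	SSRGroup 99	WBPHYN	Potential SSR	PentaSSR	P0000044	15034	15043	ATATA	2	Intergenic
4	SSRGroup 99	WBPHTA	Potential SSR	PentaSSR	P0000044	15035	15044	ATATA	2	Intergenic
5	SSRGroup 103	WBPHYN	Potential SSR	HexaSSR	H0000021	10498	10509	TAAAAG	2	CYTB
5	SSRGroup 103	WBPHHN	Potential SSR	HexaSSR	H0000021	10498	10509	TAAAAG	2	CYTB
6	Singleton 1	WBPHHN	Potential SSR	PentaSSR	P0000022	10016	10025	AATTT	2	Intergenic
7	Singleton 2	WBPHHN	Potential SSR	PentaSSR	P0000044	15034	15043	ATATA	2	Intergenic
8	Singleton 3	WBPHTA	Potential SSR	PentaSSR	P0000023	10337	10346	TACAC	2	Intergenic
9	Singleton 4	WBPHTA	Potential SSR	PentaSSR	P0000047	15347	15356	AATAA	2	Intergenic
10	Singleton 5	WBPHTA	Potential SSR	HexaSSR	H0000021	10502	10513	TAAAAG	2	Intergenic
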