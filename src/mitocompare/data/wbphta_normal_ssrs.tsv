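no	name	ssr_type	type	start	end	unit_sequence	repeat_count	gene
1	M0000001	Normal SSR	MonoSSR	858	868	A	11	ND2
2	M0000002	Normal SSR	MonoSSR	7044	7053	A	10	ND5
3	M0000003	Normal SSR	MonoSSR	7725	7737	A	13	ND5
4	M0000004	Normal SSR	MonoSSR	7830	7839	A	10	ND4
5	M0000005	Normal SSR	MonoSSR	8110	8123	A	14	ND4
6	M0000006	Normal SSR	MonoSSR	8412	8421	A	10	ND4
7	M0000007	Normal SSR	MonoSSR	8717	8727	A	11	ND4
8	M0000008	Normal SSR	MonoSSR	9057	9066	A	10	ND4
9	M0000009	Normal SSR	MonoSSR	10023	10032	T	10
10	M0000010	Normal SSR	MonoSSR	10033	10064	A	32
11	M0000011	Normal SSR	MonoSSR	11819	11830	A	12	ND1
12	M0000012	Normal SSR	MonoSSR	14555	14569	T	15
13	M0000013	Normal SSR	MonoSSR	14966	14988	T	23
14	D0000001	Normal SSR	DiSSR	14785	14796	TA	6
15	D0000002	Normal SSR	DiSSR	14862	14873	TA	6
16	D0000003	Normal SSR	DiSSR	15106	15115	AT	5
17	D0000004	Normal SSR	DiSSR	15147	15160	AT	7
18	D0000005	Normal SSR	DiSSR	15192	15201	AT	5
19	D0000006	Normal SSR	DiSSR	15208	15223	TA	8
20	D0000007	Normal SSR	DiSSR	15244	15253	TA	5
21	D0000008	Normal SSR	DiSSR	15274	15285	TA	6
22	D0000009	Normal SSR	DiSSR	15335	15344	TA	5
23	D0000010	Normal SSR	DiSSR	15387	15396	TA	5
24	T0000001	Normal SSR	TriSSR	15117	15128	ATT	4
25	Te0000001	Normal SSR	TetraSSR	8443	8454	ATAA	3	ND4
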