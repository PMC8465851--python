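mz	auc_aaa_vs_evar	auc_aaa_vs_taa	auc_evar_vs_taa	mh_calc	score	sequence	gene	protein
976.43	0.62	0.35	0.22	976.4468194	88.56	AGFAGDDAPR	ACTA2	Actin, aortic smooth muscle
1198.65	0.66	0.29	0.10	1198.51941	57.19	DSYVGDEAQSK	ACTA2	Actin, aortic smooth muscle
1198.65	0.66	0.29	0.10	1198.703002	41.77	AVFPSIVGRPR	ACTA2	Actin, aortic smooth muscle
1580.684	0.56	0.45	0.39	1580.800411	43.04	MQKEITALAPSTMK	ACTA2	Actin, aortic smooth muscle
1790.904	0.57	0.36	0.27	1790.891339	28.06	SYELPDGQVITIGNER	ACTA2	Actin, aortic smooth muscle
1564.883	0.59	0.42	0.33	1564.905355	31.49	SIVVSPILIPENQR	CDH13	Cadherin-13
1835.908	0.58	0.44	0.34	1836.842546	32.84	MTAFDADDPATDNALLR	CDH13	Cadherin-13
836.417	0.59	0.42	0.31	836.4361428	49.08	GPAGPQGPR	COL1A1	Collagen alpha-1(I) chain
852.418	0.61	0.40	0.28	851.4249814	43.88	GFSGLDGAK	COL1A1	Collagen alpha-1(I) chain
868.42	0.59	0.42	0.31	868.4253882	34.63	GEAGPQGPR	COL1A1	Collagen alpha-1(I) chain
886.421	0.56	0.43	0.36	886.4359955	47.39	GSEGPQGVR	COL1A1	Collagen alpha-1(I) chain
784.412	0.58	0.45	0.37	785.3889089	48.12	GDQGPVGR	COL1A2	Collagen alpha-2(I) chain
1561.883	0.60	0.48	0.37	1562.79067	87.57	GETGPSGPVGPAGAVGPR	COL1A2	Collagen alpha-2(I) chain
1237.653	0.57	0.43	0.37	1238.651334	47.18	VAVFFSNTPTR	COL6A3	Collagen alpha-3(VI) chain
1459.673	0.61	0.43	0.32	1459.860756	25.39	IGDLHPQIVNLLK	COL6A3	Collagen alpha-3(VI) chain
1462.674	0.55	0.44	0.39	1462.763096	27.26	QINVGNALEYVSR	COL6A3	Collagen alpha-3(VI) chain
1508.678	0.60	0.40	0.32	1507.799786	83.26	LSVEALNSLTGEFK	CKM	Creatine kinase M-type
1508.678	0.60	0.40	0.32	1507.699725	58.36	GGDDLDPNYVLSSR	CKM	Creatine kinase M-type
1767.902	0.57	0.47	0.39	1768.83488	32.75	DGEVVSEATQQQHEVL	DES	Desmin
2088.931	0.56	0.45	0.39	2088.091512	51.57	TFGGAPGFPLGSPLSSPVFPR	DES	Desmin
853.418	0.61	0.40	0.27	853.5233919	55.31	LGPLQVAR	ETFB	Electron transfer flavoprotein subunit beta
1340.663	0.60	0.44	0.34	1339.720602	51.07	LSVISVEDPPQR	ETFB	Electron transfer flavoprotein subunit beta
974.429	0.56	0.43	0.38	973.6021152	45.36	SGVSLAALKK	H1-3	Histone H1.3
1106.641	0.58	0.42	0.32	1107.565851	47.87	ALAAAGYDVEK	H1-3	Histone H1.3
1198.65	0.66	0.29	0.10	1198.666651	64.14	ASGPPVSELITK	H1-3	Histone H1.3
1325.661	0.59	0.44	0.36	1325.752447	45.61	DNIQGITKPAIR	H4C1	Histone H4
1466.674	0.60	0.42	0.32	1466.801839	61.03	TVTAMDVVYALKR	H4C1	Histone H4
1533.68	0.58	0.44	0.34	1533.775171	82.04	VVDSLQTSLDAETR	MYO6	Myosin-6
1850.909	0.59	0.44	0.34	1851.041427	48.84	VQLLHSQNTSLINQKK	MYO6	Myosin-6
2088.931	0.56	0.45	0.39	2088.123001	33.09	YRILNPVAIPEGQFIDSR	MYO6	Myosin-6
2199.941	0.57	0.46	0.39	2200.123705	49.68	GTLEDQIIQANPALEAFGNAK	MYO6	Myosin-6
976.43	0.62	0.35	0.22	975.4887038	36.63	AMEAVAAQGK	PGAM2	Phosphoglycerate mutase 2
1150.645	0.56	0.43	0.38	1150.666958	45.55	VLIAAHGNSLR	PGAM2	Phosphoglycerate mutase 2
875.42	0.57	0.44	0.37	875.4465169	30.27	SLEAQAEK	TPM1	Tropomyosin alpha-1 chain
1460.674	0.62	0.43	0.31	1460.731208	39.4	KATDAEADVASLNR	TPM1	Tropomyosin alpha-1 chain
1516.679	0.61	0.43	0.32	1516.819568	27.34	SKQLEDELVSLQK	TPM1	Tropomyosin alpha-1 chain
1305.659	0.58	0.41	0.34	1306.638768	44.38	KNIDALSGMEGR	TNNI3	Troponin I, cardiac muscle
1479.675	0.54	0.43	0.40	1479.727686	42.27	ISADAMMQALLGAR	TNNI3	Troponin I, cardiac muscle
1889.913	0.57	0.46	0.38	1890.031221	44.46	NITEIADLTQKIFDLR	TNNI3	Troponin I, cardiac muscle
758.41	0.55	0.45	0.40	757.4673223	35.39	ILAERR	TNNT2	Troponin T, cardiac muscle
906.423	0.55	0.43	0.37	906.5021046	26.65	YEINVLR	TNNT2	Troponin T, cardiac muscle
1797.904	0.57	0.46	0.40	1796.934971	29.11	SFMPNLVPPKIPDGER	TNNT2	Troponin T, cardiac muscle
1143.445	0.60	0.42	0.31	1143.632775	28.94	LAVNMVPFPR	TUBB	Tubulin beta chain
1320.661	0.64	0.38	0.24	1319.701066	49.82	IMNTFSVVPSPK	TUBB	Tubulin beta chain
1269.656	0.56	0.43	0.37	1270.559399	37.39	LGDLYEEEMR	VIM	Vimentin
1428.671	0.55	0.33	0.28	1428.710851	40.41	SLYASSPGGVYATR	VIM	Vimentin
2498.168	0.55	0.49	0.44	2497.256473	42.86	LLQDSVDFSLADAINTEFKNTR	VIM	Vimentin
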