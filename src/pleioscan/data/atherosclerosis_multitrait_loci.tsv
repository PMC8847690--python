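traits	locus_name	sentinel	chrom	pos	effect_allele	other_allele	direction	eaf	p_multi	p_trait1	p_trait2	p_trait3
PAD,CAD,T2D	SATB1	rs9845140	3	18728878	C	A	-/-/-	0.27	2.06E-11	2.59E-05	8.18E-06	2.09E-05
PAD,CAD,HDL	LRCH1	rs9526214	13	47237213	T	C	-/-/-	0.24	3.38E-11	6.17E-06	7.06E-05	8.31E-04
PAD,CAD	CTGE1/CTGE2	rs948386	18	19998810	G	C	-/-	0.42	4.10E-11	2.20E-05	1.49E-07	NA
PAD,LDL	PCSK6	rs1531817	15	101906737	C	A	+/+	0.68	3.15E-10	4.72E-04	6.48E-08	NA
PAD,CAD,TG	SAMD8	rs9299525	10	76878025	G	A	-/-/-	0.58	5.73E-10	2.35E-05	2.15E-05	5.30E-04
PAD,CAD	NFAT5	rs1364063	16	69588572	T	C	+/+	0.59	6.63E-10	6.27E-08	2.17E-05	NA
PAD,CAD,T2D	SPP2C	rs55660209	17	43932173	T	C	-/-/-	0.79	6.68E-10	7.41E-04	5.18E-04	7.41E-06
PAD,CAD,BMI	PNPLA3	rs2076211	22	44329078	C	T	+/+/+	0.84	7.56E-10	2.47E-03	4.55E-04	3.13E-06
PAD,CAD,SMK	HMBS	rs1006195	11	118958869	G	T	-/-/-	0.60	1.92E-09	2.97E-04	1.03E-06	3.90E-03
PAD,CAD	SATB1	rs9826966	3	18737796	A	G	-/-	0.27	2.14E-09	2.53E-05	4.01E-06	NA
PAD,TG	ATAD5	rs7342938	17	29189830	A	G	+/+	0.88	2.45E-09	1.86E-04	2.47E-07	NA
PAD,T2D	ARL17	rs2458203	17	44336651	T	C	-/-	0.67	3.11E-09	3.51E-03	8.36E-08	NA
PAD,TG	NUP85	rs2291031	17	73228173	C	T	+/+	0.82	3.55E-09	2.50E-03	7.45E-08	NA
PAD,T2D	ZN536	rs73022871	19	30990705	C	G	+/+	0.85	4.70E-09	2.48E-03	1.29E-07	NA
PAD,LDL	BPTF	rs12602912	17	65870073	C	T	-/-	0.79	5.24E-09	1.20E-06	2.42E-05	NA
PAD,BMI	OPN5	rs9381618	6	47780081	T	C	-/-	0.72	6.35E-09	1.24E-05	9.57E-07	NA
PAD,TG	OR4CD	rs10839321	11	49670562	T	C	-/-	0.91	6.51E-09	3.86E-03	1.08E-07	NA
PAD,CAD,SMK	ZN268	rs61960706	12	133777822	G	A	-/-/-	0.74	7.18E-09	2.56E-03	3.27E-05	6.10E-04
PAD,CAD	VDAC2	rs7088974	10	76891096	T	C	-/-	0.57	7.73E-09	1.26E-05	2.08E-05	NA
PAD,TG	ATG7	rs2606736	3	11400249	C	T	-/-	0.38	8.21E-09	2.59E-03	1.73E-07	NA
PAD,CAD	CBPC2	rs11602961	11	47727748	C	T	-/-	0.94	8.83E-09	5.81E-04	2.07E-06	NA
PAD,T2D	L2HDH	rs72683923	14	50735947	T	C	+/+	0.98	9.75E-09	7.24E-05	1.24E-06	NA
PAD,T2D	MPPD2	rs1765131	11	30404538	G	C	+/+	0.65	1.05E-08	1.45E-04	1.43E-06	NA
PAD,TC	S4A8	rs9795910	12	51795623	A	G	+/+	0.62	1.83E-08	1.81E-03	1.04E-06	NA
PAD,TC	SORCS3	rs11599236	10	106454672	T	C	+/+	0.59	2.38E-08	3.66E-05	1.24E-05	NA
PAD,BMI	LTOR3	rs185238112	4	100801033	C	T	-/-	0.94	2.49E-08	1.59E-03	7.91E-07	NA
PAD,SMK	KPCD1	rs10149845	14	30177079	C	T	-/-	0.59	3.00E-08	3.92E-05	2.10E-05	NA
PAD,T2D	SATB1	rs4269101	3	18763543	T	G	-/-	0.28	3.59E-08	1.95E-05	5.78E-06	NA
PAD,LDL	S4A8	rs9795910	12	51795623	A	G	+/+	0.62	3.86E-08	1.81E-03	2.72E-06	NA
PAD,BMI	CDKL1	rs11570792	14	50847010	C	T	+/+	0.95	4.13E-08	1.39E-03	1.39E-06	NA
PAD,CAD,TG	TMM18	rs2867113	2	651365	G	A	+/+/+	0.82	4.67E-08	1.14E-03	1.50E-04	1.15E-03
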