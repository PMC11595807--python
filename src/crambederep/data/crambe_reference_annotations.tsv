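idx	mz	rt	z	mw_printed	formula	ppm_printed	fragments	identification	family	m	n	isomer	footnote	shared_with
1	282.1806	8.16	1	281.1728	C14H23N3O3	-2.28	246.1587:1|264.1706:1|114.9612:1|60.0562:1	guanidine-related compound (C14H23N3O3)	guanidine_related
2	282.1806	9.34	1	281.1728	C14H23N3O3	-2.13	114.9611:1|60.0562:1|223.1323:1	guanidine-related compound (C14H23N3O3)	guanidine_related
3	264.1704	9.66	1	263.1626	C14H21N3O2	-0.99	246.1604:1|60.0562:1	guanidine-related compound (C14H21N3O2)	guanidine_related
IS1	355.2012	9.80	1	354.1934	C21H26N2O3	-0.75	144.0807:1|212.1274:1	yohimbine	internal_standard
4	296.1964	10.44	1	295.1886	C15H25N3O3	-1.52	237.1476:1|205.1217:1|60.0562:1|159.1160:1	guanidine-related compound (C15H25N3O3)	guanidine_related
5	227.1803	10.46	2	452.3450	C23H44N6O3	-3.31	174.1600:1|148.6021:2	crambescin C 452 homologue (m = 5, n = 4)	C	5	4
6	234.1884	10.77	2	466.3612	C24H46N6O3	-1.93	188.1756:1|155.6100:2	crambescin C 466 homologue (m = 6, n = 4)	C	6	4
7	234.1884	10.77	2		C24H46N6O3		174.1600:1|148.6021:2	crambescin C 466 homologue (m = 5, n = 5)	C	5	5			6
8	218.1757	10.87	2	434.3357	C23H42N6O2	-0.65	197.1646:2|174.1600:1|148.1095:2|220.1689:1	crambescin A 434 homologue (m = 5, n = 4)	A	5	4
9	227.1803	10.88	2	452.3450	C23H44N6O3	-3.32	128.1431:1|174.1599:1|111.0442:1|284.1956:1	crambescin B 452 homologue (m = 5, n = 4)	B	5	4
10	234.1884	10.98	2	466.3612	C24H46N6O3	-1.91	160.1441:1|141.5942:2	crambescin C1 466 (m = 4, n = 6)	C	4	6
11	241.1961	11.14	2	480.3765	C25H48N6O3	-2.42	188.1756:1|155.6096:2	crambescin C 480 homologue (m = 6, n = 5)	C	6	5
12	225.1835	11.16	2	448.3514	C24H44N6O2	-0.45	204.1722:2|188.1756:1|155.1178:2|220.1689:1	crambescin A 448 homologue (m = 6, n = 4)	A	6	4
13	292.8887	11.18	3	875.6426	C44H87N6O11	1.73	246.1587:1|139.0751:1|162.1598:1|381.3460:1	crambescidin 875	crambescidin
14	234.1884	11.18	2	466.3612	C24H46N6O3	-1.93	128.1432:1|111.0443:1|188.1757:1|298.2129:1	crambescin B 466 homologue (m = 6, n = 4)	B	6	4
15	279.2133	11.19	3	834.6166	C45H82N6O8	-1.01	246.1586:1|264.1707:1|70.0657:1|139.0750:1	crambescidin 834	crambescidin				d
16	241.1961	11.24	2	480.3765	C25H48N6O3	-2.46	174.1600:1|148.6021:2	crambescin C1 480 (m = 5, n = 6)	C	5	6
17	218.1757	11.27	2	434.3357	C23H42N6O2	-0.58	127.0864:2|197.1646:2|132.1130:1|262.2150:1	crambescin A2 434 (m = 2, n = 7)	A	2	7
18	249.1829	11.33	2	496.3502	C28H44N6O2	-2.79	114.1028:1|384.2650:1|132.1131:1|228.1724:2	crambescin A3 496 (m = 2) (cis)	A3	2		cis
19	225.1834	11.36	2	448.3513	C24H44N6O2	-0.78	204.1722:2|141.1018:2|160.1441:1|248.2002:1	crambescin A1 448 (m = 4, n = 6)	A	4	6
20	234.1884	11.43	2	466.3612	C24H46N6O3	-1.93	132.1131:1|127.5783:2	crambescin C2 466 (m = 2, n = 8)	C	2	8
21	234.1884	11.43	2		C24H46N6O3		156.1748:1|111.0443:1|160.1441:1	crambescin B1 466 (m = 4, n = 6)	B	4	6			20
22	248.2038	11.49	2	494.3921	C26H50N6O3	-2.46	188.1756:1|155.6091:2	crambescin C1 494 (m = 6, n = 6)	C	6	6
23	238.1909	11.51	2	474.3662	C26H46N6O2	-2.02	188.1756:1|217.1806:2|155.1178:2|170.1650:1	didehydrocrambescin A1 474 (m = 6, n = 6)	didehydroA	6	6
24	241.1960	11.55	2	480.3765	C25H48N6O3	-2.58	142.1585:1|111.0443:1|188.1756:1|298.2106:1	crambescin B 480 homologue (m = 6, n = 5)	B	6	5
25	256.1910	11.55	2	510.3664	C29H46N6O2	-1.57	128.1178:1|384.2652:1|235.1809:2|146.1287:1	crambescin A3 510 (m = 3) (cis)	A3	3		cis
26	249.1829	11.62	2	496.3502	C28H44N6O2	-2.73	132.1131:1|114.1028:1|127.0864:2|384.2638:1	crambescin A3 496 (m = 2) (trans)	A3	2		trans
27	232.1909	11.62	2	462.3663	C25H46N6O2	-1.99	211.1798:2|174.1599:1|148.1093:1|248.2003:1	crambescin A1 462 (m = 5, n = 6)	A	5	6
28	241.1961	11.68	2	480.3765	C25H48N6O3	-2.46	156.1749:1|111.0443:1|174.1600:1|284.1957:1	crambescin B1 480 (m = 5, n = 6)	B	5	6
29	248.2039	11.68	2	494.3921	C26H50N6O3	-2.40	132.1131:1|127.0865:2|114.1026:1	crambescin C2 494 (m = 2, n = 10)	C	2	10
30	225.1835	11.70	2	448.3513	C24H44N6O2	-0.64	127.0863:2|204.1721:2|132.1130:1|276.2321:1	crambescin A2 448 (m = 2, n = 8)	A	2	8
31	272.2038	11.71	2	542.3920	C30H50N6O3	-2.40	160.1441:1|142.1335:1	crambescin C3 542 (m = 4)	C3	4
32	267.8778	11.73	3	800.6100	C45H80N6O6	-2.50	70.0657:1|349.2648:2|206.1536:1|392.3078:2	crambescidin 800 or isocrambescidin 800	crambescidin				d
33	263.1990	11.79	2	524.3824	C30H48N6O2	-0.76	142.1334:1|384.2649:1|160.1440:1|242.1875:2	crambescin A3 524 (m = 4) (cis)	A3	4		cis
34	256.1910	11.81	2	510.3664	C29H46N6O2	-1.65	146.1287:1|134.0943:2|128.1178:1|235.1805:2	crambescin A3 510 (m = 3) (trans)	A3	3		trans
35	286.8851	11.83	3	857.6318	C44H85N6O10	1.41	264.1703:1|139.0749:1|246.1602:1|381.3456:1	crambescidin 857	crambescidin
36	273.2094	11.84	3	816.6048	C45H80N6O7	-2.53	264.1707:1|246.1587:1|139.0751:1|70.0657:1	crambescidin 816	crambescidin				d
37	234.1884	11.88	2	466.3613	C24H46N6O3	-1.77	184.2054:1|132.1131:1|114.1028:1|242.1484:1	crambescin B2 466 (m = 2, n = 8)	B	2	8
38	239.1989	11.90	2	476.3821	C26H48N6O2	-1.39	188.1756:1|156.174:1|111.0443:1|218.1873:2	crambescin A1 476 (m = 6, n = 6)	A	6	6
39	281.5530	11.94	3	841.6355	C44H85N6O9	-0.20	263.1982:1|70.0657:1|116.1071:1|139.0751:1	crambescidin 841	crambescidin
40	267.8778	11.94	3	800.6099	C45H80N6O6	-2.58	70.0657:1|349.2647:2|392.3078:2|206.1537:1	crambescidin 800 or isocrambescidin 800	crambescidin				d
41	248.2039	11.94	2	494.3921	C26H50N6O3	-2.34	156.1749:1|111.0444:1|188.1756:1|298.2130:1	crambescin B1 494 (m = 6, n = 6)	B	6	6
42	232.1910	11.98	2	462.3664	C25H46N6O2	-1.73	211.1799:2|134.0942:2|146.1287:1|276.2325:1	crambescin A 462 homologue (m = 3, n = 8)	A	3	8
43	238.1908	11.98	2	474.3659	C26H46N6O2	-2.74	127.0864:2|132.1131:1|217.1807:2|114.1028:1	didehydrocrambescin A2 474 (m = 2, n = 10)	didehydroA	2	10
44	270.2066	12.03	2	538.3977	C31H50N6O2	-1.36	497.3828:1|384.2652:1|522.3766:1|174.1602:1	crambescin A3 538 (m = 5) (cis)	A3	5		cis	c
45	263.1990	12.03	2	524.3825	C30H48N6O2	-0.63	160.1441:1|141.1018:2|242.1877:2|384.2650:1	crambescin A3 524 (m = 4) (trans)	A3	4		trans
46	232.1910	12.11	2	462.3664	C25H46N6O2	-1.82	127.0864:2|211.1799:2|132.113:1|290.2473:1	crambescin A2 462 (m = 2, n = 9)	A	2	9
47	416.3195	12.16	2	830.6233	C46H82N6O7	0.98	264.1707:1|246.1587:1|70.0657:1|139.0751:1	crambescidin 830	crambescidin
48	272.2037	12.18	2	542.3917	C30H50N6O3	-2.92	160.1441:1|111.0443:1|232.2046:1|274.2275:1	crambescin B3 542 (m = 4)	B3	4
49	270.2066	12.27	2	538.3976	C31H50N6O2	-1.49	174.1597:1|148.1098:2|249.1955:2|156.1493:1	crambescin A3 538 (m = 5) (trans)	A3	5		trans
50	404.2534	12.32	1	403.2463	C22H33O4N3	-1.74	360.2640:1|206.1536:1|342.2542:1|60.0562:1	crambescidin acid	crambescidin_acid
51	239.1988	12.51	2	476.3820	C26H48N6O2	-1.65	127.0864:2|218.1873:2|132.113:1|304.2617:1	crambescin A2 476 (m = 2, n = 10)	A	2	10
52	254.2221	12.51	1	253.2148	C14H27N3O	-1.97	195.1740:1|97.0651:1|60.0562:1|111.0442:1	crambescin 253	small_crambescin
IS2	609.2800	12.59	1	608.2722	C33H40N2O9	-0.22	195.0642:1|174.0913:1|397.2098:1|448.1952:1	reserpine	internal_standard
53	282.2534	13.77	1	281.2460	C16H31N3O	-1.42	114.9612:1|223.2051:1|97.0651:1|60.0562:1	crambescin 281	small_crambescin
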