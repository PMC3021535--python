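site	fold	pxbar	hse_offset	cytology	staining	genes	tss_distance	location
3R:17121946..17122005	96	1.10E-07	98	93D		Hsrw	-368	Intergenic
2L:13165433..13165492	76	3.70E-11	-161	34A	1	Sir2 & DnaJ-H	-532	Intergenic
3R:19883079..19883127	75	6.80E-08	25	95D	2.5	Hsp68	-74	Intergenic
3L:9351650..9351707	75	8.80E-08	0	67B	4	Hsp26 & Hsp67Ba	-3051707	Intergenic
3R:7783512..7783571	73	2.00E-10	-447	87A	3	Hsp70Ab & Hsp70Aa	-1760	Intergenic
2L:295186..295245	73	3.20E-09	74	21B	1	Hop	108	Exon1
3L:3176534..3176591	71	7.60E-08	-102	63B	3	Hsp83	5	Exon1
3L:9357629..9357688	70	6.70E-08	-3	67B	4	Hsp27 & Hsp23	-3521829	Intergenic
3R:11068766..11068825	65	3.60E-12	22	88E	1.5	Hsc70-4	-81	Intergenic
3L:22008546..22008605	60	1.60E-05	-51	79B		CG7133	-213	Intergenic
3L:9347685..9347744	58	1.90E-04	-142	67B	4	Hsp22 & Hsp67Bb	-249838	Intergenic
X:20846528..20846587	54	1.20E-06	-123	19E		Ntf-2	409	Intron1
X:5725222..5725281	52	1.00E-07	-62	5C	2	CG16721	159	Exon1
3R:27045350..27045409	49	1.70E-07	NA	100B	1	CG1746	-23	Intergenic
3L:16745454..16745513	48	2.10E-07	133	73C	1	CG9705	115	Exon1
2L:22342021..22342080	46	2.20E-11	135	40F	1.5	CG17018	42528	Intron1
X:10954037..10954096	42	2.30E-07	77	10A	1	Hsp60	377	Intron1
3L:12990240..12990299	38	2.00E-07	88	69F		CG11267	267	Intron1
2L:6966386..6966445	38	9.80E-12	-25	27C		smt3	1177	downstream
3R:12473487..12473539	37	7.30E-12	15	89D	1	Cctgamma	102	Exon1
3L:13454266..13454312	36	5.50E-07	3	70B		stv	-101	Intergenic
3L:3886074..3886133	36	2.40E-07	32	63F		Ubi-p63E	348	Exon2
2L:5009864..5009923	36	2.40E-08	-16	25C	1	Rtnl1	-150	Intergenic
3R:9208591..9208650	36	2.60E-11	107	87E	2	Droj2	78	Exon1
2L:12046460..12046519	35	2.40E-11	218	33B	3	CG6770	-390	Intergenic
3R:11072836..11072895	35	1.20E-11	17	88E	1.5	Hsc70-4	2889	downstream
3L:7839477..7839536	35	6.10E-07	-6	66A		Pdp1	1812	Intron1
3L:17877705..17877764	34	4.30E-07	-30	75A	3	CG5290	81	Exon1
3L:8492559..8492618	34	1.00E-06	186	66D	2	CG6776	-245	Intergenic
X:11204481..11204540	34	2.50E-06	48	10B	2	CG11750	57	Exon1
X:2503300..2503359	33	1.60E-07	6	3A	1	sgg	2182	Intron1
X:6499517..6499576	33	1.30E-07	106	6C		CG3226	-125	Intergenic
2L:22157037..22157096	32	2.40E-11	NA	40F	1.5	CG1832	-313	Intergenic
U:5800980..5801039	32	1.20E-07	40	53F	0.5	CAP	1331	Intron2
3R:25608959..25609018	32	6.10E-07	13	99C		kay	657	Intron1
3R:3859259..3859318	31	4.50E-11	89	84E	2	Tom34 & CG11035	263 & -620	Intron1
3L:112600..112659	31	2.40E-07	16	61B		Pk61C	-353	Intergenic
3L:8678764..8678823	31	3.10E-07	86	66D	2
3L:14002678..14002737	30	1.30E-07	171	70C	1	Hsc70Cb	195	Exon1
2L:16517060..16517119	30	8.20E-11	NA	36A	1.5	CG5953	11716	Intron2
3L:19838272..19838331	30	1.80E-06	-31	76D		Su(Tpl)	5748	Intron1
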