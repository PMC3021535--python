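gene	fold_cells	p_cells	fold_larvae	p_larvae	tss_distance	chip_fold	chip_pxbar
DnaJ-1	5.3	3.25E-08	42	2.11E-05	219	27	1.18E-07
Hsp22	14.1	3.70E-09	227	3.29E-08	-249	58	1.91E-04
Hsp26	12.2	1.43E-09	28.5	1.12E-04	-305	75	8.76E-08
Hsp27	8.8	7.56E-07	7.5	1.78E-04	-352	70	6.69E-08
Hsp67Bb	2.1	7.53E-04	14.1	1.58E-04	838	58	1.91E-04
Hsp68	24.7	2.24E-10	106.8	4.23E-08	-74	75	6.82E-08
Hsp70Ab	31.7	3.30E-09	169.9	8.76E-10	-732	73	1.95E-10
stv	3.9	3.73E-08	29.4	7.13E-10	-421	36	5.50E-07
CG32636	2.5	6.24E-04	3.9	4.60E-04	315	12	1.15E-06
CG10924	1.5	1.70E-01	2.5	1.12E-04	2156	17	1.44E-10
CG10973	1.2	2.51E-02	3.8	8.58E-03	97	20	2.30E-07
CG11033	1.1	2.37E-01	2.1	9.46E-04	-740	28	1.46E-04
CG11035	-1.6	1.69E-02	5.3	9.67E-08	-620	31	4.50E-11
CG13472	-1.1	1.55E-01	3	3.24E-04	115	12	9.33E-06
CG1416	-1.1	1.32E-01	2.7	8.87E-04	410	7	1.35E-08
CG1553	-1.1	2.19E-01	4.4	8.86E-08	144	19	9.64E-11
CG1863	-1.1	5.19E-01	5.6	7.49E-04	909	16	1.17E-10
CG32103	-1	9.83E-01	2.3	3.60E-03	-472	5	7.73E-05
CG3226	1.1	2.38E-01	3	6.09E-05	-125	33	1.25E-07
CG5010	1.1	6.17E-01	3.4	1.27E-03	-376	26	1.70E-07
CG5290	-1	8.58E-01	15.3	6.80E-08	81	34	4.31E-07
CG5953	-1	8.89E-01	2.9	8.41E-04	2125	6	1.96E-06
CG6191	-1.3	1.47E-03	2.2	1.93E-03	1430	16	8.42E-11
CG6511	-1.1	2.96E-02	7.8	1.34E-06	36	28	2.24E-07
CG7945	1.1	7.28E-01	5.2	1.13E-05	345	17	9.31E-06
CG9153	-1.1	3.34E-01	2.6	6.02E-04	260	26	1.93E-07
Droj2	-1.1	1.56E-01	2.7	2.57E-04	823	36	2.57E-11
GstD10	1.6	5.04E-02	2.3	2.40E-05	-447	7	6.25E-07
Hop	-1.1	2.39E-01	2.9	1.22E-04	108	73	3.23E-09
Hsc70-3	1.1	2.39E-01	2.9	4.24E-04	1721	11	5.00E-05
Hsc70-4	-1.1	1.03E-01	2.1	3.16E-06	-123	65	3.64E-12
Hsc70-5	-1.1	8.90E-02	3.4	2.17E-05	236	18	1.05E-10
Hsc70Cb	-1.1	2.35E-01	2.7	1.47E-04	195	30	1.31E-07
Hsp83	1.3	2.40E-03	15.1	2.69E-06	5	71	7.58E-08
PEK	-1.2	1.14E-01	3.7	3.83E-04	1048	6	5.22E-05
Pdk	-1.1	5.87E-01	2.6	6.91E-05	4359	10	4.05E-10
Sir2	-1	9.09E-01	2.8	9.63E-03	-87	76	3.73E-11
Taf7	1.1	1.44E-01	7.3	6.86E-05	353	18	7.06E-11
Tom34	-1.1	3.90E-01	6.5	9.74E-05	263	31	4.50E-11
cn	-1.4	3.13E-01	2.2	4.62E-04	2174	17	1.25E-09
l(1)G0469	1.8	3.85E-03	3.8	6.01E-03	2448	21	5.05E-07
mbf1	1.2	5.24E-02	2.3	1.96E-04	-67	28	1.20E-06
pall	1.1	2.57E-01	3.3	4.90E-04	497	5	6.21E-05
sra	1	9.32E-01	3.3	1.99E-03	25	18	1.86E-10
tra	-1.1	2.42E-01	3.2	4.37E-03	248	5	1.10E-04
ttk	1.7	7.65E-03	2.3	3.18E-03	2452	13	7.08E-05
CG10077	2.7	4.10E-03	7.8	1.38E-02	-104	22	4.39E-07
CG6770	3	1.25E-03	1.7	2.03E-01	-390	35	2.43E-11
GstD2	-2.2	4.66E-03	-1.3	4.43E-01	-1110	6	1.23E-08
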