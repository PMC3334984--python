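pool	accession	platform	read_length	read_count_million	coverage
1	Armking	shortread	94	5.85	2.42
1	Big Top	shortread	94	3.55	1.47
1	Fidelia	shortread	94	6.47	2.68
1	Flordastar	shortread	94	7.27	3.01
1	Silver Rome	shortread	94	8.35	3.45
1	Weinberger	shortread	94	9.72	4.02
2	Babygold 8	shortread	93	5.60	2.29
2	Elberta	shortread	93	5.63	2.30
2	Maruja	shortread	93	8.52	3.49
2	Maycrest	shortread	93	8.61	3.52
2	Oro A	shortread	93	7.20	2.95
2	Stark Red Gold	shortread	93	6.37	2.61
3	Circe	shortread	93	9.23	3.78
3	Imera	shortread	93	5.92	2.42
3	Percoca di Romagna 7	shortread	93	4.27	1.75
3	Pillar	shortread	93	1.40	0.57
3	S 2678	shortread	93	10.15	4.15
3	Stark Saturn	shortread	93	7.45	3.05
4	Kamarat	shortread	93	9.63	3.94
4	Leonforte 1	shortread	93	2.32	0.95
4	Sahua Hong Pantao	shortread	93	19.20	7.86
4	Shen Zhou Mitao	shortread	93	12.54	5.13
4	Tabacchiera	shortread	93	0.56	0.23
4	Tudia	shortread	93	7.43	3.04
5	GF677	shortread	93	9.22	3.77
5	Kurakata Wase	shortread	93	6.75	2.76
5	Quetta	shortread	93	12.76	5.22
5	S6699	shortread	93	4.90	2.01
6	Admiral Dewey	shortread	80	2.42	0.85
6	Babcock	shortread	80	3.19	1.12
6	Elberta	shortread	80	0.64	0.23
6	Slappey	shortread	80	2.02	0.71
7	Bolinha	shortread	80	3.55	1.25
7	Carmen	shortread	80	1.66	0.58
7	Chinese Cling	shortread	80	2.50	0.88
7	Mayflower	shortread	80	1.35	0.47
8	Diamante	shortread	80	2.11	0.74
8	J.H. Hale	shortread	80	3.18	1.12
8	Rio Oso Gem	shortread	80	2.57	0.91
8	Yellow St. John	shortread	80	1.35	0.48
9	Dixon	shortread	80	1.25	0.44
9	Early Crawford	shortread	80	3.89	1.37
9	Florida Prince	shortread	80	1.85	0.65
9	Nonpareil	shortread	80	2.52	0.89
10	Dr. Davis	shortread	80	2.31	0.81
10	Nemaguard	shortread	80	2.38	0.84
10	O'Henry	shortread	80	4.28	1.51
10	Okinawa	shortread	80	2.15	0.76
11	Georgia Belle	shortread	80	14.42	5.08
11	Lovell	shortread	80	6.55	2.30
11	Lovell	shortread	80	0.03	0.01
11	Oldmixon Free	shortread	80	3.26	1.15
12	Big Top	longread	330	0.20	0.29
12	Binaced	longread	355	0.16	0.26
12	Catherina	longread	288	0.17	0.22
12	Elegant Lady	longread	243	0.19	0.20
12	Nectaross	longread	275	0.19	0.23
12	O'Henry	longread	289	0.15	0.18
12	Sweet Cap	longread	251	0.16	0.18
12	Venus	longread	278	0.15	0.19
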