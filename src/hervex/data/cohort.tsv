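group	specimen_id	pmi_hours	age	sex	collection_year	hq_reads_millions
control	202	4	57	M	1983	91.5
control	214	4	56	M	1981	94.7
control	3276	19	54	M	2002	93.9
control	33	5	69	M	1983	89.1
control	3371	16	52	M	2002	96.8
control	3406	20	72	F	2002	89.3
control	3465	20	93	F	2002	105.2
control	3482	14	79	F	2003	97.5
control	3543	12	73	F	2003	105.2
control	3348	9	76	F	2002	102.7
control	3465b	11	76	M	2003	107.3
control	3637	13	76	M	2003	102.5
control	3641	20	76	M	2003	85.3
control	3698	17	84	F	2003	90.3
demyelination	168	3	37	F	1984	89.7
demyelination	2443	26	49	F	1997	99
demyelination	2485	9	69	M	1997	63.3
demyelination	2696	21	86	F	1998	130.9
demyelination	2946	15	59	M	1999	88.9
demyelination	3161	20	51	F	2001	89.9
demyelination	3185	14	50	M	2001	91.1
demyelination	3509	11	74	F	2003	87.2
demyelination	3816	21	47	F	2004	91
demyelination	3840	23	61	F	2003	95
demyelination	3931	10	74	F	2004	73.8
demyelination	5149	8	48	M	2010	66.4
demyelination	108	2	56	F	1998	72.5
demyelination	290	NA	NA	NA	NA	82.3
OND	1418	5	68	M	1988	76.8
OND	4403	18	77	F	2006	99.5
OND	4471	12	73	F	2007	49.4
OND	710	8	58	M	1983	50.1
OND	924	24	86	M	1985	67.9
OND	coloradoA	NA	NA	NA	NA	67.9
OND	coloradoB	NA	NA	NA	NA	66.9
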