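sample	ccs_reads	on_target	cag1	cag2	ccg1	ccg2
1	5902	195	21	36	7	7
2	7317	125	17	18	10	10
3	9892	301	17	23	7	7
4	5775	117	15	38	10	7
5	33415	261	17	35	10	7
6	11590	160	20	27	7	7
7	4862	88	17	41	10	7
8	6025	84	17	25	10	9
9	10624	132	17	39	7	7
10	13500	186	21	29	7	7
11	5852	75	15	54	10	7
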