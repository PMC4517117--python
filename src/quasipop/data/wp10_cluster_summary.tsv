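cluster	nucleotide	n_loci	mean_frequency_pct	snps_per_genome	cluster_snps_per_ob
1	A	903	0.23	1.39	137.71
1	T	969	0.20	1.44	137.71
1	G	328	0.44	0.87	137.71
1	C	361	0.36	0.89	137.71
2	A	98	8.97	7.07	933.75
2	T	104	8.77	7.41	933.75
2	G	112	10.02	9.79	933.75
2	C	86	9.43	6.86	933.75
3	A	39	16.75	5.94	842.56
3	T	41	16.31	6.35	842.56
3	G	46	23.59	9.72	842.56
3	C	38	19.92	6.07	842.56
4	A	25	35.82	6.03	901.33
4	T	25	34.86	5.10	901.33
4	G	30	35.99	7.95	901.33
4	C	38	32.91	10.96	901.33
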