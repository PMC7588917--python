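# Published per-transcript reference values for Ceriporiopsis subvermispora
# lignocellulolytic genes: codon adaptation index (CAI) with its genome-wide
# Z-score, and two-condition microarray signals (log2, glucose vs ball-milled
# aspen; GEO accession GSE34636, JGI Cersu1 genome). ratio_published is the
# BMA/glucose fold change as printed at three decimals; group_published is
# the stated induction class where one was described (B = induced >= 2-fold,
# p < 0.05; C = not significant). Used as worked-example inputs only.
id	family	CAI	Z_CAI	log2_glucose	log2_bma	ratio_published	p_value	group_published
49863	peroxidase	0.814	1.236	9.58	11.15	2.970	0.08320
50297	peroxidase	0.822	1.394	13.13	11.88	0.421	0.19000	C
50686	peroxidase	0.823	1.414	9.35	9.42	1.048	0.45600
106380	peroxidase	0.815	1.255	8.93	8.93	1.000	0.99900
111364	peroxidase	0.770	0.364	9.18	9.11	0.957	0.52800
117521	peroxidase	0.819	1.335	9.57	9.49	0.945	0.30600
124144	peroxidase	0.696	-1.101	11.30	11.21	0.942	0.29300
126018	peroxidase	0.828	1.513	9.69	9.50	0.874	0.10000
126058	peroxidase	0.788	0.721	9.94	9.44	0.707	0.00595
128590	peroxidase	0.824	1.434	9.78	9.52	0.837	0.01960
129418	peroxidase	0.767	0.305	10.22	12.92	6.508	0.00895	B
130659	peroxidase	0.781	0.582	10.88	10.30	0.673	0.03900
136058	peroxidase	0.770	0.364	10.16	10.76	1.519	0.16700
151947	peroxidase	0.831	1.572	9.00	8.93	0.955	0.24200
155372	peroxidase	0.797	0.899	8.86	8.84	0.988	0.74100
169968	peroxidase	0.816	1.275	10.27	10.16	0.930	0.44200
130783	laccase	0.791	0.780	11.02	13.77	6.766	0.00426	B
67561	cellulose_binding	0.853	2.008	10.30	13.71	10.642	0.00002	B
84792	cdh	0.803	1.018	9.29	13.76	22.241	0.00002	B
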