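mirna_id	tpm_a	tpm_b	printed_log2fc	printed_p	printed_label
cre-miR-new1	0.65	1.17	0.8381	0.163
cre-miR-new2	64.68	33.15	-0.9644	7.98e-34
cre-miR-new3	34.08	22.85	-0.5765	1.89e-8
cre-miR-new4	129.80	88.87	-0.5464	1.38e-25
cre-miR-new5	2.47	16.33	2.7280	2.96e-13	**
cre-miR-new6	1.23	1.51	0.2926	0.542
cre-miR-new7	95.14	123.33	0.3744	0
cre-miR-new8	0.87	4.60	2.4017	3.45e-7	**
cre-miR-new9	0.65	1.44	1.1430	0.046	*
cre-miR-new10	0.87	1.10	0.3356	0.553
cre-miR-new11	88.39	139.45	0.6578	1.41e-13
cre-miR-new12	1.89	3.23	0.7748	0.026
cre-miR-new13	7.90	7.89	-0.0021	0.989
cre-miR-new14	33.28	9.95	-1.7418	5.51e-43	**
cre-miR-new15	179.25	170.61	-0.0712	0.08
cre-miR-new16	3.55	7.76	1.1261	2.23e-6	**
cre-miR-new17	0.65	3.02	2.2101	4.22e-6	**
cre-miR-new18	8.77	20.11	1.1965	3.55e-14	**
cre-miR-new19	365.68	132.11	-1.4688	0	**
cre-miR-new20	5.80	73.84	3.6701	0	**
cre-miR-new21	18.20	23.95	0.3961	8.60e-4
cre-miR-new22	72.66	142.06	0.9674	2.63e-13
cre-miR-new23	24.58	50.79	1.0468	1.79e-13	**
cre-miR-new24	0.00	4.25	b_only	2.22e-16
cre-miR-new25	0.00	12.63	b_only	2.22e-16
cre-miR-new26	7.18	0.00	a_only	9.70e-32
cre-miR-new27	5.44	0.00	a_only	3.18e-24
cre-miR-new28	17.98	0.00	a_only	2.13e-78
cre-miR-new29	29.80	0.00	a_only	1.93e-129
cre-miR-new30	44.88	0.00	a_only	1.42e-194
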