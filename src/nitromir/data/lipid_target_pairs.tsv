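mirna_id	mirna_fold_change	mirna_direction	gene_product	target_fold_change	target_direction	printed_p
cre-miR1156.2	0.35	Down	Prosaposin	2.17	Up	0
cre-miR1144a.2	2.04	Up	SAM-dependent methyltransferases	0.07	Down	2.12e-38
cre-miR1144a.2	2.04	Up	Animal-type fatty acid synthase and related proteins	0.24	Down	0.302
cre-miR1157*	1.25	Up	Cytochrome P450 CYP4/CYP19/CYP26 subfamilies	0.76	Down	0.284
cre-miR1163.1	16.71	Up	Fatty acid desaturase	0.28	Down	4.921e-2
cre-miR1163.1	16.71	Up	Sterol C5 desaturase	0.86	Down	0.611
cre-miR1163.1	16.71	Up	START domain-containing proteins	1.25	Up	1.55e-3
cre-miR1169	2.98	Up	Lysophospholipase	0.60	Down	0.135
cre-miR910	15.55	Up	acyl-CoA oxidase	1.34	Up	4.70e-2
cre-miR-new5	6.61	Up	Putative phosphoinositide phosphatase	0.35	Down	0.146
cre-miR-new14	0.30	Down	3-Methylcrotonyl-CoA carboxylase	3.66	Up	0
cre-miR-new16	2.19	Up	Long-chain acyl-CoA transporter	0.46	Down	4.66e-3
cre-miR-new19	0.36	Down	Acyl-CoA synthetase	4.13	Up	3.24e-12
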