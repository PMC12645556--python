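protein_id	fold_change	q_value	n_peptides
P4ha2	1.975703	0.032448	2
Prepl	1.890943	0.031788	2
Tfrc	1.808806	0.034181	2
Cdk5rap3	1.584465	0.04171	2
Stim1	1.430249	0.041519	2
Rpn2	1.411756	0.031788	2
Mcu	1.410518	0.031788	2
Sacs	1.408841	0.027333	2
Mrpl9	1.386239	0.036035	2
Rps6ka3	1.337576	0.02735	2
Osbp	1.306942	0.015255	2
Eif3l	1.282809	0.031788	2
Otud4	1.271351	0.031795	2
Iars1	1.251002	0.043284	2
Cbr1	0.765177	0.027333	2
Mdh1	0.744469	0.015255	2
Nme2	0.728192	0.022598	2
Ldhb	0.70785	0.036035	2
Acy1	0.705856	0.031788	2
Gatd3	0.701152	0.031788	2
Gstp1	0.649432	0.011138	2
Kyat3	0.646493	0.011138	2
Got1	0.640539	0.015255	2
Gstm2	0.634352	0.013451	2
Selenbp1	0.630464	0.015255	2
Spr	0.630359	0.011138	2
Rpl4	0.613312	0.015255	2
Rpl7	0.611864	0.015255	2
Rpl13	0.611216	0.037633	2
Gstm1	0.602801	0.013451	2
Mb	0.559002	0.015255	2
Bckdhb	0.550348	0.021111	2
Gpx3	0.449778	0.011138	2
IGHG3	0.448368	0.011138	2
Rpl28	0.445844	0.011138	2
Nqo1	0.434254	0.011138	2
HVM51	0.389294	0.017207	2
Igh-3	0.273444	0.011138	2
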