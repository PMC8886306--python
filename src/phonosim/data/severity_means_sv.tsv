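pattern	clinical_mean	clinical_sd	wcm_mean	wcm_sd	ipc_mean	ipc_sd	pcc_mean	pcc_sd	lvn_mean	lvn_sd	pwp_mean	pwp_sd
weak_syllable_deletion	4.85	1.5	-0.06	0.36	-0.09	0.55	99	7	0.01	0.05	0.98	0.09
backing	4.70	1.3	0.51	0.68	0.60	0.87	68	39	0.12	0.14	0.90	0.13
stopping	4.18	1.1	-0.33	0.70	-0.29	0.58	88	27	0.04	0.09	0.95	0.10
fronting	3.03	0.80	-0.20	0.45	-0.32	0.76	93	19	0.03	0.07	0.97	0.08
cluster_reduction	2.88	1.3	-0.15	0.45	-0.14	0.56	98	8	0.00	0.02	0.98	0.07
r_weakening	1.36	1.0	0.11	0.34	0.00	0.00	96	13	0.02	0.05	0.99	0.04
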