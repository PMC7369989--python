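genus	n_species	n_p450s	n_families	n_subfamilies	dominant_family	n_bgcs	n_bgc_species	n_p450s_in_bgcs
Streptomyces	203	5460	253	698	CYP107	4457	144	1231
Mycobacterium	60	1784	77	132	CYP125	898	60	204
Bacillus	128	507	13	28	CYP107	1098	128	112
Cyanobacteria	114	341	36	79	CYP110	770	103	27
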