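group	flux	control	control_norm	e0.5	e0.5_norm	e1	e1_norm
main	hk	0.0901118	1	0.12	1	0.135	1
main	pfk	0.0968532	1.07481	0.120985	1.00821	0.135572	1.004237
main	fbpase	0.00716729	0.07954	1.46E-3	0.01219	0.0009715	0.007197
main	pep->g3p	0.00694225	0.07704	0.00749499	0.06246	0.0025560	0.018933
main	g3p->pep	0.186074	2.06492	0.246177	2.05148	0.271442	2.010681
main	pk	0.181224	2.01110	0.253755	2.11463	0.28068	2.079111
main	TCA->pyr	2.23E-3	0.02470	0.0152166	0.12681	0.0118396	0.087701
main	lac->	0.12219	1.35598	0.153661	1.28051	0.128901	0.954822
main	pdh	0.057984	0.64347	0.0815881	0.67990	0.140089	1.037696
main	pc	1.05E-3	0.01165	0.0185053	0.15421	0.0116895	0.086589
main	CitSyn	0.0351159	0.38969	0.0547404	0.45617	0.120038	0.889170
main	cit->mal	0.0366362	0.40656	0.0549581	0.45798	0.120969	0.896067
main	PPP	1.32E-4	1.47E-3	2.80E-6	2.33E-5	3.93E-6	2.91E-5
main	r5p->	4.38E-4	0.00486	6.84E-4	0.00570	0.0005799	0.004296
main	cit->glt	3.50E-3	0.03884	2.13E-3	0.01775	0.0014090	0.010437
main	->cit	0.00549634	0.06099	2.35E-3	0.01959	0.0023398	0.017332
tk	xu5p->s7p	0.00826654	0.09174	2.26E-7	1.88E-6	1.46E-6	1.08E-5
tk	s7p->xu5p	0.0084719	0.09402	4.24E-4	0.00353	0.0003579	0.002651
tk	f6p->xu5p	5.66E-4	0.00628	3.54E-5	0.00030	3.03E-5	0.000224
tk	xu5p->f6p	5.38E-4	0.00597	3.45E-9	2.87E-8	1.89E-8	1.40E-7
tk	f6p->s7p	0.00534401	0.05930	2.46E-4	0.00205	0.0001979	0.001466
tk	s7p->f6p	0.0052113	0.05783	4.49E-5	0.00037	3.08E-5	0.000228
tk	xu5p<->g3p	8.75E-4	9.71E-3	3.26E-8	2.71E-7	2.21E-7	1.64E-6
tk	f6p<->e4p	3.48E-4	0.00386	3.75E-6	3.12E-5	2.63E-6	1.95E-5
tk	r5p<->s7p	0.0800302	0.88812	2.94E-3	0.02453	0.0023626	0.017501
ta	f6p->s7p	1.54E-4	0.00171	2.57E-4	0.00214	0.0002003	0.001484
ta	s7p->f6p	2.48E-5	0.00028	2.25E-5	0.00019	4.54E-6	3.36E-5
ta	f6p<->g3p	2.64E-7	2.93E-6	1.09E-6	9.05E-6	2.51E-7	1.86E-6
ta	s7p<->e4p	0.0144573	0.16044	0.0053368	0.04447	0.0037384	0.027691
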