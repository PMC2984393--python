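condition	metabolite	mass_shift	fraction	sd	fit
control	lactate	0	0.7900	0.003	0.7900
control	lactate	1	0.0097	0.001	0.0096
control	lactate	2	0.1990	0.003	0.1990
control	lactate	3	0.0013	0.001	0.0013
control	ribose	0	0.5480	0.011	0.5480
control	ribose	1	0.2310	0.004	0.2310
control	ribose	2	0.1490	0.005	0.1490
control	ribose	3	0.0423	0.001	0.0420
control	ribose	4	0.0299	0.001	0.0296
e0.5	lactate	0	0.7860	0.001	0.7860
e0.5	lactate	1	0.0099	0.000	0.0099
e0.5	lactate	2	0.2030	0.001	0.2030
e0.5	lactate	3	0.0013	0.001	0.0013
e0.5	ribose	0	0.5570	0.003	0.5570
e0.5	ribose	1	0.2210	0.007	0.2250
e0.5	ribose	2	0.1410	0.003	0.1430
e0.5	ribose	3	0.0483	0.005	0.0449
e0.5	ribose	4	0.0325	0.002	0.0293
e1	lactate	0	0.7910	0.003	0.7920
e1	lactate	1	0.0098	0.001	0.0098
e1	lactate	2	0.1980	0.003	0.1970
e1	lactate	3	0.0010	0.002	0.0011
e1	ribose	0	0.5790	0.011	0.5790
e1	ribose	1	0.2130	0.004	0.2110
e1	ribose	2	0.1340	0.005	0.1390
e1	ribose	3	0.0426	0.001	0.0418
e1	ribose	4	0.0312	0.001	0.0291
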