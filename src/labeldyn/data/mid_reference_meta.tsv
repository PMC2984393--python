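condition	dilution	chi2
control	0.3450	0.1760
e0.5	0.2080	4.7400
e1	0.2920	5.7500
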