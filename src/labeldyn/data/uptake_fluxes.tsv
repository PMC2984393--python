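condition	J_Glc	J_Lac
control	0.09	0.1225
e0.5	0.1196	0.1565
e1	0.1359	0.1279
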