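condition,metabolite,n0,nt,t_min,c_start,c_end,volume_per_1e6_cells
control,glucose,0.25,0.36,2880,8.66,4.76,0.05
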