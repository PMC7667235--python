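parameter	Nyctaginia_capitata	Boerhavia_coccinea	Allionia_incarnata
a400	7.0	23.0	26.8
a1200	23.5	31.3	30.5
a400_a1200	0.30	0.74	0.88
wue	100	158	149
ci_ca	0.58	0.31	0.35
initial_slope	0.05	0.25	0.36
slope_over_a1200	0.002	0.008	0.012
gamma	75	4.5	2.5
pepc_area	15.1	111.8	131.7
pepc_per_chl	27.0	261.9	429.7
nadp_me_area	0	50.1	0
nadp_me_per_chl	0	116.7	0
nad_me_area	0	2.1	27.7
nad_me_per_chl	0	5.1	91.5
chlorophyll	0.56	0.43	0.30
chl_ab_ratio	3.46	4.45	3.67
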