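species	pathway	family	copy	rpkm
Mirabilis jalapa	C3	PEPC	PEPC1	164
Mirabilis jalapa	C3	PEPC	PEPC2	19
Mirabilis jalapa	C3	PEPC	PEPC3	105
Mirabilis jalapa	C3	NAD-ME	NAD1	50
Mirabilis jalapa	C3	NAD-ME	NAD2	28
Mirabilis jalapa	C3	NAD-ME	NAD3	4
Mirabilis jalapa	C3	NADP-ME	NADP1	122
Mirabilis jalapa	C3	NADP-ME	NADP2	4
Mirabilis jalapa	C3	NADP-ME	NADP3	75
Allionia incarnata	C4	PEPC	PEPC1	12069
Allionia incarnata	C4	PEPC	PEPC2	33
Allionia incarnata	C4	PEPC	PEPC3	88
Allionia incarnata	C4	NAD-ME	NAD1	80
Allionia incarnata	C4	NAD-ME	NAD2	25
Allionia incarnata	C4	NAD-ME	NAD3	2001
Allionia incarnata	C4	NADP-ME	NADP1	1751
Allionia incarnata	C4	NADP-ME	NADP2	114
Allionia incarnata	C4	NADP-ME	NADP3	13
Boerhavia burburgiana	C4	PEPC	PEPC1	17742
Boerhavia burburgiana	C4	PEPC	PEPC2	1
Boerhavia burburgiana	C4	PEPC	PEPC3	144
Boerhavia burburgiana	C4	NAD-ME	NAD1	56
Boerhavia burburgiana	C4	NAD-ME	NAD2	6
Boerhavia burburgiana	C4	NAD-ME	NAD3	0.4
Boerhavia burburgiana	C4	NADP-ME	NADP1	8563
Boerhavia burburgiana	C4	NADP-ME	NADP2	2
Boerhavia burburgiana	C4	NADP-ME	NADP3	144
Boerhavia coccinea	C4	PEPC	PEPC1	9331
Boerhavia coccinea	C4	PEPC	PEPC2	0.1
Boerhavia coccinea	C4	PEPC	PEPC3	128
Boerhavia coccinea	C4	NAD-ME	NAD1	85
Boerhavia coccinea	C4	NAD-ME	NAD2	27
Boerhavia coccinea	C4	NAD-ME	NAD3	0.2
Boerhavia coccinea	C4	NADP-ME	NADP1	3562
Boerhavia coccinea	C4	NADP-ME	NADP2	2
Boerhavia coccinea	C4	NADP-ME	NADP3	121
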