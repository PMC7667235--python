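tribe	genus	n_sampled	d13c_min	d13c_max
Boldoeae	Salpianthus	3	-28.8	-27.4
Bougainvilleeae	Phaeoptilum	1	-24.4	-24.4
Caribeeae	Cryptocarpus	1	-27.2	-27.2
Colignonieae	Colignonia	6	-28.7	-25.3
Leucastereae	Andradea	1	-26.0	-26.0
Leucastereae	Leucaster	1	-28.8	-28.8
Leucastereae	Ramisia	1	-24.3	-24.3
Nyctagineae	Abronia	20	-29.5	-24.5
Nyctagineae	Acleisanthes	14	-28.0	-23.9
Nyctagineae	Allionia	2	-13.3	-13.2
Nyctagineae	Anulocaulis	5	-28.0	-24.2
Nyctagineae	Boerhavia	43	-14.9	-9.4
Nyctagineae	Commicarpus	23	-28.7	-25.2
Nyctagineae	Cyphomeris	2	-28.1	-27.2
Nyctagineae	Mirabilis	23	-29.8	-22.6
Nyctagineae	Nyctaginia	1	-26.2	-26.2
Nyctagineae	Okenia	4	-14.0	-12.3
Nyctagineae	Tripterocalyx	4	-27.8	-24.9
Pisonieae	Pisoniella	1	-25.8	-25.8
Pisonieae	Grajalesia	1	-25.7	-25.7
Pisonieae	Cephalotomandra	1	-28.8	-28.8
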