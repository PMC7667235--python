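taxon	pathway
Mirabilis	C3
Commicarpus	C3
Allionia	C4
Cyphomeris	C3
Anulocaulis	C3
Nyctaginia	C3
Okenia	C4
Boerhavia	C4
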