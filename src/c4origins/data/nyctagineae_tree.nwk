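(Mirabilis,(Commicarpus,((Allionia,Cyphomeris),((Anulocaulis,Nyctaginia),(Okenia,Boerhavia)))));
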