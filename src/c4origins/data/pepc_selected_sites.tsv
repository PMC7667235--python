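position	confidence	c3_residue	c4_grass_residues
466	p>0.999	Met	Ile,Val
517	p>0.999	Thr	Ala,Cys
531	p>0.999	Ala	Pro
560	p>0.999	Arg	Pro
572	p>0.99	Glu	Gln
577	p>0.999	Ser	Ser
579	p>0.999	Ala	Glu
599	p>0.99	Ile	Val
625	p>0.999	Val	Ala
637	p>0.999	Met	Leu,Phe
665	p>0.95	His	Asn
733	p>0.95	Phe	Met,Val
761	p>0.999	Ser	Ala
780	p>0.999	Ala	Ser
794	p>0.999	Phe	Val
807	p>0.999	Arg	Lys
813	p>0.99	Arg	Gln
863	p>0.95	Asn	Lys
866	p>0.95	Glu	Glu
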