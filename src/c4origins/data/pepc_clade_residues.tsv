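clade	position	residues
Boerhavia/Okenia	466	Met
Boerhavia/Okenia	517	Thr
Boerhavia/Okenia	531	Ala
Boerhavia/Okenia	560	Arg
Boerhavia/Okenia	572	Gln
Boerhavia/Okenia	577	Ser
Boerhavia/Okenia	579	Ala
Boerhavia/Okenia	599	Ile
Boerhavia/Okenia	625	Leu
Boerhavia/Okenia	637	Met
Boerhavia/Okenia	665	His
Boerhavia/Okenia	733	Met
Boerhavia/Okenia	761	Ala
Boerhavia/Okenia	780	Ala
Boerhavia/Okenia	794	Phe
Boerhavia/Okenia	807	Lys
Boerhavia/Okenia	813	Arg,Gln
Boerhavia/Okenia	863	Lys
Boerhavia/Okenia	866	Glu
Allionia	466	Met
Allionia	517	Thr
Allionia	531	Ala
Allionia	560	Arg
Allionia	572	Gln
Allionia	577	Ser
Allionia	579	Ala
Allionia	599	Ile
Allionia	625	Val
Allionia	637	Met
Allionia	665	His
Allionia	733	Phe
Allionia	761	Ala
Allionia	780	Ala
Allionia	794	Phe
Allionia	807	Lys
Allionia	813	Gln
Allionia	863	Asn
Allionia	866	Glu
C3_Nyctaginaceae	466	Met
C3_Nyctaginaceae	517	Thr
C3_Nyctaginaceae	531	Ala
C3_Nyctaginaceae	560	Arg
C3_Nyctaginaceae	572	Glu
C3_Nyctaginaceae	577	Ser
C3_Nyctaginaceae	579	Ala
C3_Nyctaginaceae	599	Ile
C3_Nyctaginaceae	625	Val
C3_Nyctaginaceae	637	Met
C3_Nyctaginaceae	665	His
C3_Nyctaginaceae	733	Phe
C3_Nyctaginaceae	761	Ser
C3_Nyctaginaceae	780	Ala
C3_Nyctaginaceae	794	Phe
C3_Nyctaginaceae	807	Arg
C3_Nyctaginaceae	813	Arg
C3_Nyctaginaceae	863	Asn
C3_Nyctaginaceae	866	Glu
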