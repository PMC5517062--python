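# Synthetic mini strain listing (NOT an export of MGD/RGD or any supplementary
# dataset). A small curated set of well-known mouse and rat strains/stocks with
# common synonyms and substrains, sufficient to drive the synthetic corpus
# generator and the dictionary-matching tests. Full-scale runs should supply
# real MGD/RGD-style listings via `compile_strain_dictionary`.
# columns: species <TAB> name <TAB> strain_type <TAB> synonyms(|) <TAB> substrains(|)
mouse	C57BL	inbred	C57 black|c57Black|c57/black|Black 6|Black6|BL6|C56BL	C57BL/6J|C57BL/6N|C57BL/10
mouse	BALB/c	inbred	Balb-c|BALB	BALB/cJ|BALB/cByJ
mouse	Swiss	outbred	Swiss Webster|Swiss albino
mouse	ICR	outbred	CD-1|Institute of Cancer Research
mouse	NMRI	outbred
mouse	CF-1	outbred	Carworth Farms 1
mouse	C3H	inbred		C3H/HeJ|C3H/HeN
mouse	DBA	inbred		DBA/2J|DBA/1J
mouse	AKR	inbred		AKR/NCr|AKR/J
mouse	NOD	inbred	non obese diabetic|nonobese diabetic	NOD/ShiLtJ
mouse	ob/ob	other	ob-ob|obese|B6.Cg-Lep ob
mouse	db/db	other	db-db|diabetic db
mouse	KKAy	other	KK-Ay|KKaY
mouse	nude	other	athymic nude|nu/nu
rat	Sprague Dawley	outbred	Sprague-Dawley|SD
rat	Wistar	outbred	Wistar albino	Wistar Han|Wistar Kyoto
rat	SHR	inbred	spontaneously hypertensive|spontaneously hypertensive rat	SHR/NCrl
rat	ZDF	other	Zucker diabetic fatty|Zucker Diabetic Fatty
rat	Zucker	other	Zucker fatty|fa/fa
rat	Lewis	inbred		LEW/Crl
rat	Fischer 344	inbred	F344|Fischer	F344/N
rat	Long Evans	outbred	Long-Evans
rat	Holtzman	outbred
rat	Dahl salt-sensitive	inbred	Dahl S|Dahl-S
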