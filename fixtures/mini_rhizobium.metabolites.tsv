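id	compartment	formula	charge	name
mal_b	b	C4H4O5	-2	mal
succ_b	b	C4H4O4	-2	succ
glu_b	b	C5H8NO4	-1	glu
ala_b	b	C3H7NO2	0	ala
nh3_b	b	H3N	0	nh3
o2_b	b	O2	0	o2
n2_b	b	N2	0	n2
h2_b	b	H2	0	h2
co2_b	b	CO2	0	co2
h2o_b	b	H2O	0	h2o
h_b	b	H	1	h
nadh_b	b	C21H27N7O14P2	-2	nadh
atp_b	b	C10H12N5O13P3	-4	atp
nad_b	b	C21H26N7O14P2	-1	nad
adp_b	b	C10H12N5O10P2	-3	adp
pi_b	b	HO4P	-2	pi
pyr_b	b	C3H3O3	-1	pyr
oaa_b	b	C4H2O5	-2	oaa
nh4_b	b	H4N	1	nh4
akg_b	b	C5H4O5	-2	akg
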