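id	compartment	formula	charge	name
photon_e	e		0	photon
co2_e	e	CO2	0	co2
o2_e	e	O2	0	o2
h2o_e	e	H2O	0	h2o
h_e	e	H	1	h
nh4_e	e	H4N	1	nh4
no3_e	e	NO3	-1	no3
hco3_e	e	CHO3	-1	hco3
starch_p	p	C6H10O5	0	starch
mal_c	c	C4H4O5	-2	mal
succ_c	c	C4H4O4	-2	succ
photon_p	p		0	photon
co2_c	c	CO2	0	co2
co2_p	p	CO2	0	co2
co2_m	m	CO2	0	co2
o2_c	c	O2	0	o2
o2_p	p	O2	0	o2
o2_m	m	O2	0	o2
h2o_c	c	H2O	0	h2o
h2o_p	p	H2O	0	h2o
h2o_m	m	H2O	0	h2o
h_c	c	H	1	h
h_m	m	H	1	h
nh4_c	c	H4N	1	nh4
no3_c	c	NO3	-1	no3
hco3_c	c	CHO3	-1	hco3
maltose_p	p	C12H22O11	0	maltose
maltose_c	c	C12H22O11	0	maltose
g6p_p	p	C6H11O9P	-2	g6p
g6p_c	c	C6H11O9P	-2	g6p
pi_c	c	HO4P	-2	pi
pi_p	p	HO4P	-2	pi
pyr_c	c	C3H3O3	-1	pyr
pyr_m	m	C3H3O3	-1	pyr
akg_m	m	C5H4O5	-2	akg
akg_c	c	C5H4O5	-2	akg
atp_m	m	C10H12N5O13P3	-4	atp
adp_c	c	C10H12N5O10P2	-3	adp
atp_c	c	C10H12N5O13P3	-4	atp
adp_m	m	C10H12N5O10P2	-3	adp
pi_m	m	HO4P	-2	pi
nadh_c	c	C21H27N7O14P2	-2	nadh
nad_m	m	C21H26N7O14P2	-1	nad
nad_c	c	C21H26N7O14P2	-1	nad
nadh_m	m	C21H27N7O14P2	-2	nadh
nadp_p	p	C21H25N7O17P3	-3	nadp
nadph_p	p	C21H26N7O17P3	-4	nadph
h_p	p	H	1	h
adp_p	p	C10H12N5O10P2	-3	adp
atp_p	p	C10H12N5O13P3	-4	atp
glc_c	c	C6H12O6	0	glc
glu_c	c	C5H8NO4	-1	glu
gln_c	c	C5H10N2O3	0	gln
ala_c	c	C3H7NO2	0	ala
suc_c	c	C12H22O11	0	suc
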