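id	equation	lb	ub	gpr	kind	objective	name
EX_mal	mal_b ->	-1000	0		exchange		
EX_succ	succ_b ->	-1000	0		exchange		
EX_glu	glu_b ->	-1000	0		exchange		
EX_ala	ala_b ->	0	1000		exchange		
EX_nh3	nh3_b ->	0	1000		exchange		
EX_o2	o2_b ->	-1000	0		exchange		
EX_n2	n2_b ->	-1000	0		exchange		
EX_h2	h2_b ->	0	1000		exchange		
EX_co2	co2_b <=>	-1000	1000		exchange		
EX_h2o	h2o_b <=>	-1000	1000		exchange		
EX_h	h_b <=>	-1000	1000		exchange		
NIF	16 atp_b + 16 h2o_b + n2_b + 4 nadh_b -> 16 adp_b + h2_b + 12 h_b + 4 nad_b + 2 nh3_b + 16 pi_b	0	1000	g_nifH	internal		
ME	mal_b + nad_b -> co2_b + nadh_b + pyr_b	0	1000	g_dme	internal		
MDH	mal_b + nad_b <=> h_b + nadh_b + oaa_b	-1000	1000	g_mdh	internal		
SDH_FUM	h2o_b + nad_b + succ_b -> h_b + mal_b + nadh_b	0	1000	g_sdh	internal		
PYC	atp_b + co2_b + h2o_b + pyr_b <=> adp_b + 2 h_b + oaa_b + pi_b	-1000	1000	g_pyc	internal		
ALADH	h_b + nadh_b + nh4_b + pyr_b -> ala_b + h2o_b + nad_b	0	1000	g_alaDH	internal		
NH4EQ	h_b + nh3_b <=> nh4_b	-1000	1000		internal		
GPT	glu_b + pyr_b <=> akg_b + ala_b	-1000	1000	g_gpt	internal		
AKGDH_SCS	adp_b + akg_b + nad_b + pi_b -> atp_b + co2_b + nadh_b + succ_b	0	1000	g_sucCD	internal		
PDH_TCA	adp_b + 2 h2o_b + 5 nad_b + pi_b + pyr_b -> atp_b + 3 co2_b + 3 h_b + 5 nadh_b	0	1000	g_pdh	internal		
OXPHOS	2.5 adp_b + 3.5 h_b + nadh_b + 0.5 o2_b + 2.5 pi_b -> 2.5 atp_b + 3.5 h2o_b + nad_b	0	1000	g_cox	internal		
MAINT	atp_b + h2o_b -> adp_b + h_b + pi_b	0	1000		maintenance		
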