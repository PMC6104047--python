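id	equation	lb	ub	gpr	kind	objective	name
EX_photon	photon_e ->	-100	0		exchange		
EX_co2	co2_e <=>	-1000	1000		exchange		
EX_o2	o2_e <=>	-1000	1000		exchange		
EX_h2o	h2o_e <=>	-1000	1000		exchange		
EX_h	h_e <=>	-1000	1000		exchange		
EX_nh4	nh4_e ->	-1000	0		exchange		
EX_no3	no3_e ->	-1000	0		exchange		
EX_hco3	hco3_e <=>	-1000	1000		exchange		
EX_starch	starch_p <=>	-1000	1000		exchange		
EX_mal	mal_c ->	0	1000		exchange		
EX_succ	succ_c ->	0	1000		exchange		
T_photon	photon_e -> photon_p	0	1000	g_t_photon	transport		
T_co2	co2_e <=> co2_c	-1000	1000	g_t_co2	transport		
T_co2_p	co2_c <=> co2_p	-1000	1000	g_t_co2_p	transport		
T_co2_m	co2_c <=> co2_m	-1000	1000	g_t_co2_m	transport		
T_o2	o2_e <=> o2_c	-1000	1000	g_t_o2	transport		
T_o2_p	o2_p <=> o2_c	-1000	1000	g_t_o2_p	transport		
T_o2_m	o2_c <=> o2_m	-1000	1000	g_t_o2_m	transport		
T_h2o	h2o_e <=> h2o_c	-1000	1000	g_t_h2o	transport		
T_h2o_p	h2o_c <=> h2o_p	-1000	1000	g_t_h2o_p	transport		
T_h2o_m	h2o_c <=> h2o_m	-1000	1000	g_t_h2o_m	transport		
T_h	h_c <=> h_e	-1000	1000	g_t_h	transport		
T_h_m	h_c <=> h_m	-1000	1000	g_t_h_m	transport		
T_nh4	nh4_e -> nh4_c	0	1000	g_t_nh4	transport		
T_no3	no3_e -> no3_c	0	1000	g_t_no3	transport		
T_hco3	hco3_c <=> hco3_e	-1000	1000	g_t_hco3	transport		
MEX	maltose_p -> maltose_c	0	1000	g_mex	transport		
T_g6p	g6p_p <=> g6p_c	-1000	1000	g_t_g6p	transport		
T_pi_p	pi_c <=> pi_p	-1000	1000	g_t_pi_p	transport		
T_pyr	pyr_c <=> pyr_m	-1000	1000	g_t_pyr	transport		
T_akg	akg_m -> akg_c	0	1000	g_t_akg	transport		
T_atp	adp_c + atp_m -> adp_m + atp_c	0	1000	g_t_atp	transport		
T_pi_m	pi_c <=> pi_m	-1000	1000	g_t_pi_m	transport		
SHUTTLE_NADH	nad_m + nadh_c <=> nad_c + nadh_m	-1000	1000	g_shuttle_nadh	transport		
PSII	2 h2o_p + 2 nadp_p + 8 photon_p -> 2 h_p + 2 nadph_p + o2_p	0	1000	g_psii	internal		
PHOTOPHOS	adp_p + h_p + 4 photon_p + pi_p -> atp_p + h2o_p	0	1000	g_photophos	internal		
CALVIN	18 atp_p + 6 co2_p + 11 h2o_p + 12 nadph_p -> 18 adp_p + g6p_p + 6 h_p + 12 nadp_p + 17 pi_p	0	1000	g_calvin	internal		
STARCH_SYN	atp_p + g6p_p + h2o_p -> adp_p + h_p + 2 pi_p + starch_p	0	1000	g_starch_syn	internal		
STARCH_DEG	h2o_p + 2 starch_p -> maltose_p	0	1000	g_starch_deg	internal		
MALTASE	h2o_c + maltose_c -> 2 glc_c	0	1000	g_maltase	internal		
HXK	atp_c + glc_c -> adp_c + g6p_c + h_c	0	1000	g_hxk	internal		
GLYC	3 adp_c + g6p_c + 2 nad_c + 2 pi_c -> 3 atp_c + 2 h2o_c + h_c + 2 nadh_c + 2 pyr_c	0	1000	g_glyc	internal		
CA	co2_c + h2o_c <=> h_c + hco3_c	-1000	1000	g_ca	internal		
NR	6 h_c + 4 nadh_c + no3_c -> 3 h2o_c + 4 nad_c + nh4_c	0	1000	g_nr	internal		
GS_GOGAT	akg_c + atp_c + nadh_c + nh4_c -> adp_c + glu_c + nad_c + pi_c	0	1000	g_gs_gogat	internal		
GDH	glu_c + h2o_c + nad_c <=> akg_c + h_c + nadh_c + nh4_c	-1000	1000	g_gdh	internal		
GLN_SYN	atp_c + glu_c + nh4_c -> adp_c + gln_c + h_c + pi_c	0	1000	g_gln_syn	internal		
ALT	glu_c + pyr_c <=> akg_c + ala_c	-1000	1000	g_alt	internal		
SUC_SYN	2 g6p_c + h2o_c -> 2 pi_c + suc_c	0	1000	g_suc_syn	internal		
INV	h2o_c + suc_c -> 2 glc_c	0	1000	g_inv	internal		
MAL_SYN	co2_c + nadh_c + pyr_c -> mal_c + nad_c	0	1000	g_mal_syn	internal		
SUCC_SYN	h_c + mal_c + nadh_c -> h2o_c + nad_c + succ_c	0	1000	g_succ_syn	internal		
PDH_TCA	adp_m + 2 h2o_m + 5 nad_m + pi_m + pyr_m -> atp_m + 3 co2_m + 3 h_m + 5 nadh_m	0	1000	g_pdh_tca	internal		
AKG_SYN	atp_m + 2 h2o_m + 2 nad_m + 2 pyr_m -> adp_m + akg_m + co2_m + 3 h_m + 2 nadh_m + pi_m	0	1000	g_akg_syn	internal		
OXPHOS	2.5 adp_m + 3.5 h_m + nadh_m + 0.5 o2_m + 2.5 pi_m -> 2.5 atp_m + 3.5 h2o_m + nad_m	0	1000	g_oxphos	internal		
MAINT	atp_c + h2o_c -> adp_c + h_c + pi_c	1	1000		maintenance		
BIOMASS	0.1 ala_c + 6 atp_c + 0.25 glc_c + 0.025 gln_c + 6 h2o_c -> 6 adp_c + 6 h_c + 6 pi_c	0	1000		biomass	1	
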