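gene_id	shoot	root
g_akg_syn	10.0	10.0
g_alt	10.0	10.0
g_ca	10.0	10.0
g_calvin	10.0	0.0
g_gdh	10.0	10.0
g_gln_syn	10.0	10.0
g_glyc	10.0	10.0
g_gs_gogat	10.0	10.0
g_hxk	10.0	10.0
g_inv	10.0	10.0
g_mal_syn	10.0	10.0
g_maltase	10.0	10.0
g_mex	10.0	10.0
g_nr	10.0	10.0
g_oxphos	10.0	10.0
g_pdh_tca	10.0	10.0
g_photophos	10.0	0.0
g_psii	10.0	0.0
g_shuttle_nadh	10.0	10.0
g_starch_deg	10.0	10.0
g_starch_syn	10.0	10.0
g_suc_syn	10.0	10.0
g_succ_syn	10.0	10.0
g_t_akg	10.0	10.0
g_t_atp	10.0	10.0
g_t_co2	10.0	10.0
g_t_co2_m	10.0	10.0
g_t_co2_p	10.0	0.0
g_t_g6p	10.0	10.0
g_t_h	10.0	10.0
g_t_h2o	10.0	10.0
g_t_h2o_m	10.0	10.0
g_t_h2o_p	10.0	10.0
g_t_h_m	10.0	10.0
g_t_hco3	10.0	10.0
g_t_nh4	10.0	10.0
g_t_no3	10.0	10.0
g_t_o2	10.0	10.0
g_t_o2_m	10.0	10.0
g_t_o2_p	10.0	0.0
g_t_photon	10.0	0.0
g_t_pi_m	10.0	10.0
g_t_pi_p	10.0	10.0
g_t_pyr	10.0	10.0
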