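constants.temperature_K = 310
bath.na_o_mM = 146
bath.k_o_mM = 4
bath.cl_o_mM = 150
bath.gluc_o_mM = 6
bath.na_s_mM = 146
bath.k_s_mM = 4
bath.cl_s_mM = 150
bath.gluc_s_mM = 6
bath.p_o_atm = 1
bath.p_s_atm = 1
am.p_na_m_s = 2.4e-10
am.lp_m_s_pa = 1.12848896e-09
lm.p_k_m_s = 3.540801364e-07
lm.p_cl_m_s = 1.600127821e-10
lm.lp_m_s_pa = 5.252537079e-12
sm.p_k_m_s = 6.937438021e-09
sm.p_cl_m_s = 3.42649079e-08
sm.lp_m_s_pa = 4.138992153e-11
tj.p_na_m_s = 6.78720054e-09
tj.p_k_m_s = 1.615419136e-08
tj.p_cl_m_s = 1.300852204e-05
tj.p_gluc_m_s = 1.326273435e-10
tj.lp_m_s_pa = 3.417377645e-11
tj.sigma_na = 0.7
tj.sigma_k = 0.7
tj.sigma_cl = 0.45
tj.sigma_gluc = 0.8
ibm.p_na_m_s = 2e-07
ibm.p_k_m_s = 7.049097414e-07
ibm.p_cl_m_s = 7.194283873e-05
ibm.p_gluc_m_s = 0.001
ibm.lp_m_s_pa = 3.928864205e-09
ibm.sigma_na = 0.03
ibm.sigma_k = 0.03
ibm.sigma_cl = 0.03
ibm.sigma_gluc = 0.03
pump.p_pump_mol_s_v_m2 = 0.0008758853144
pump.k_na_mM = 3.4
pump.k_k_mM = 0.75
pump.dg_atp_kj_mol = -58
sglt1.pmax_m_s = 7.965541854e-11
sglt1.km_mM = 1
sglt1.n_w = 264
carriers.glut1_jmax_mol_m2_s = 2.351905458e-05
carriers.glut1_k_mM = 5
carriers.k_am_nak2cl = 2.323769023e-14
carriers.k_sm_nak2cl = 0
geometry.mu_am_per_pa = 0.0039
geometry.mu_lm_per_pa = 0.008586972382
geometry.mu_sm_per_pa = 0.0039
geometry.vol_lis_ref_nl_cm2 = 25.25668014
geometry.dc_per_m2 = 1e+10
geometry.ma_mol = 1.368103286e-13
geometry.z_a = -0.95
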