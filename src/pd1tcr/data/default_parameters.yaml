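# Default kinetic constants of the PD-1/TCR/CD28 signaling model.
# Units: second-order rates (nM s)^-1, first-order rates s^-1,
# Michaelis constants nM, k_corr dimensionless.
k_dpa_yiya: 2.4e-5
k_dpi_yi: 2.4e-5
k_dpi_yiya: 1.2e-5
k_dpa_ya: 6.0e-6
k_dpa_pi: 1.2e-7
k_a_zap: 7.0e-5
k_p1_zap: 2.0e-6
k_p2_zap: 3.0e-5
k_p_lat: 1.0e-3
k_a_slp: 1.5e-2
k_p_slp: 3.0e-3
k_a_gads: 5.0e-4
k_a_pi3k: 1.4e-6
k_a_shp: 6.5e-3
k_pi_i: 6.0e-7
k_pi_ya: 6.0e-5
k_pa_i: 1.0e-6
k_pa_yi: 7.5e-4
k_p_cd3: 3.29
k_dp_cd3: 5.0
k_d_zap: 1.0e-3
k_d_slp: 0.12
k_d_gads: 1.5
k_p_cd28: 1.0
k_dp_cd28: 5.0
k_d_pi3k: 9.0e-4
k_p_pd1: 7.5
k_d1_shp: 10.0
k_dp_cp2: 5.0e-8
k_d2_shp: 1.0
KM_p_cd3: 80.0
KM_dp_cd3: 150.0
KM_p_cd28: 1000.0
KM_dp_cd28: 500.0
KM_p_pd1: 1000.0
k_corr: 41.0
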