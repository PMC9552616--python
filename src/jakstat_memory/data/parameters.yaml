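# Calibrated kinetic constants of the interferon JAK-STAT / PTP model.
# provenance: literature = fixed from prior measurements;
# fitted = calibrated against the behavioural targets of the package.
parameters:
- name: k_on
  value: 0.0001693
  units: 1/(ng/ml)/min
  provenance: fitted
- name: k_off
  value: 0.02
  units: 1/min
  provenance: fitted
- name: k_act
  value: 0.3
  units: 1/min
  provenance: fitted
- name: thalf_rg_a
  value: 110.0
  units: min
  provenance: literature
- name: thalf_ra_a
  value: 60.0
  units: min
  provenance: literature
- name: k_inh_r
  value: 4.442e-05
  units: 1/molecule/min
  provenance: fitted
- name: k_int_deg
  value: 0.005
  units: 1/min
  provenance: fitted
- name: k_recyc
  value: 0.001
  units: 1/min
  provenance: fitted
- name: k_syn_rg
  value: 6.712
  units: molecules/min
  provenance: fitted
- name: k_syn_ra
  value: 1.928
  units: molecules/min
  provenance: fitted
- name: k_deg_r
  value: 0.0007099
  units: 1/min
  provenance: fitted
- name: conv_g
  value: 1.0
  units: binding units/(ng/ml)
  provenance: fitted
- name: conv_a
  value: 1.0
  units: binding units/(ng/ml)
  provenance: fitted
- name: k_phos_s1
  value: 4.0e-05
  units: 1/molecule/min
  provenance: fitted
- name: k_dephos_s1c
  value: 0.01933
  units: 1/min
  provenance: fitted
- name: k_dim
  value: 0.001521
  units: 1/molecule/min
  provenance: fitted
- name: k_undim
  value: 0.1
  units: 1/min
  provenance: fitted
- name: k_imp_dim
  value: 0.15
  units: 1/min
  provenance: fitted
- name: k_ndiss_dim
  value: 0.015
  units: 1/min
  provenance: fitted
- name: k_ndephos_s1
  value: 0.02
  units: 1/min
  provenance: fitted
- name: k_exp_s1
  value: 0.03
  units: 1/min
  provenance: fitted
- name: k_imp_s1
  value: 0.003
  units: 1/min
  provenance: fitted
- name: k_tl_s1
  value: 2.0
  units: molecules/mRNA/min
  provenance: fitted
- name: k_deg_s1
  value: 5.0e-05
  units: 1/min
  provenance: fitted
- name: k_phos_s2
  value: 4.0e-05
  units: 1/molecule/min
  provenance: fitted
- name: k_dephos_s2c
  value: 0.05
  units: 1/min
  provenance: fitted
- name: k_het
  value: 2.0e-05
  units: 1/molecule/min
  provenance: fitted
- name: k_unhet
  value: 0.1
  units: 1/min
  provenance: fitted
- name: k_isgf3
  value: 0.0001
  units: 1/molecule/min
  provenance: fitted
- name: k_unisgf3
  value: 0.01
  units: 1/min
  provenance: fitted
- name: k_imp_het
  value: 0.1
  units: 1/min
  provenance: fitted
- name: k_imp_isgf3
  value: 0.2
  units: 1/min
  provenance: fitted
- name: k_ndiss_isgf3
  value: 0.01
  units: 1/min
  provenance: fitted
- name: k_ndiss_het
  value: 0.02
  units: 1/min
  provenance: fitted
- name: k_ndephos_s2
  value: 0.03
  units: 1/min
  provenance: fitted
- name: k_exp_s2
  value: 0.05
  units: 1/min
  provenance: fitted
- name: k_imp_s2
  value: 0.001
  units: 1/min
  provenance: fitted
- name: k_tl_s2
  value: 1.0
  units: molecules/mRNA/min
  provenance: fitted
- name: k_deg_s2
  value: 0.0002
  units: 1/min
  provenance: fitted
- name: k_syn_irf9
  value: 4.0
  units: molecules/min
  provenance: fitted
- name: k_deg_irf9
  value: 0.0001
  units: 1/min
  provenance: fitted
- name: k_imp_irf9
  value: 0.002
  units: 1/min
  provenance: fitted
- name: k_exp_irf9
  value: 0.05
  units: 1/min
  provenance: fitted
- name: k_ptp_act
  value: 0.1713
  units: 1/min
  provenance: fitted
- name: K_ract
  value: 1699.0
  units: molecules
  provenance: fitted
- name: k_chain
  value: 0.01145
  units: 1/min
  provenance: fitted
- name: k_ptp_deact
  value: 0.0004
  units: 1/min
  provenance: fitted
- name: k_ptp_on_s1
  value: 0.0002891
  units: 1/molecule/min
  provenance: fitted
- name: k_ptp_cat_s1
  value: 70.3
  units: 1/min
  provenance: fitted
- name: k_ptp_on_s2
  value: 0.0002891
  units: 1/molecule/min
  provenance: fitted
- name: k_ptp_cat_s2
  value: 70.3
  units: 1/min
  provenance: fitted
- name: ptp_total
  value: 5185.0
  units: molecules
  provenance: fitted
- name: k_txn_s1_basal
  value: 0.05
  units: mRNA/min
  provenance: fitted
- name: k_txn_s1_irf1
  value: 0.6
  units: mRNA/min
  provenance: fitted
- name: K_irf1
  value: 2000.0
  units: molecules
  provenance: fitted
- name: k_deg_ms1
  value: 0.015
  units: 1/min
  provenance: fitted
- name: k_txn_irf1_basal
  value: 0.02
  units: mRNA/min
  provenance: fitted
- name: k_txn_irf1_gas
  value: 2.0
  units: mRNA/min
  provenance: fitted
- name: K_gas
  value: 20000.0
  units: molecules
  provenance: fitted
- name: k_deg_mirf1
  value: 0.02
  units: 1/min
  provenance: fitted
- name: k_tl_irf1
  value: 0.5
  units: molecules/mRNA/min
  provenance: fitted
- name: k_deg_irf1
  value: 0.01
  units: 1/min
  provenance: fitted
- name: k_txn_s2
  value: 0.4
  units: mRNA/min
  provenance: fitted
- name: k_deg_ms2
  value: 0.02
  units: 1/min
  provenance: fitted
- name: fluor_scale
  value: 1.0
  units: a.u./molecule
  provenance: fitted
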