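{
  "k_ppx_y15": 0.1,
  "k_b55_cdc25": 1.0,
  "k_cdk1_cdc25": 2.0,
  "k_plk1_cdc25": 0.3,
  "k_cdk1_sub": 1.5,
  "k_b55_sub": 0.8,
  "cdc25_tot": 1.0,
  "cycbcdk1_tot": 1.0,
  "sub_tot": 1.0,
  "cyca_cdk2_tot": 4.0,
  "f_plk1": 1.0,
  "wee1_tot": 1.0,
  "b55_tot": 1.0,
  "aux_k_cdc25_cdk1": 4.0,
  "aux_k_ppx_t14": 0.05,
  "aux_k_wee1_cdk1": 4.0,
  "aux_k_b55_wee1": 1.0,
  "aux_k_cdk1_wee1": 4.0,
  "aux_k_cyca_wee1": 0.4,
  "aux_k_b55_act": 1.0,
  "aux_k_cdk1_b55": 4.0,
  "nebd_threshold": 0.3
}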