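gravity: 9.81
segments:
  HAT:
    mass: 53.5
    length: 0.8
    com_offset: 0.35
    inertia: 3.0
  thigh:
    mass: 8.5
    length: 0.5
    com_offset: 0.3
    inertia: 0.15
  shank:
    mass: 3.5
    length: 0.5
    com_offset: 0.3
    inertia: 0.05
  foot:
    mass: 1.25
    inertia: 0.005
    heel:
    - -0.07
    - -0.08
    ball:
    - 0.13
    - -0.08
    com:
    - 0.04
    - -0.04
hill:
  fl_width: 0.56
  fl_c: -2.99573227355
  fv_N: 1.5
  fv_K: 5.0
  see_eps_ref: 0.04
  pe_width: 0.56
  be_rel_length: 0.44
  be_width: 0.28
activation:
  tau: 0.01
muscles:
  SOL:
    F_max: 4000.0
    l_opt: 0.04
    l_slack: 0.26
    v_max: 6.0
    delay: 0.02
    S0: 0.01
    attachments:
    - joint: ankle
      r: -0.025
      phi_max_deg: 110.0
      phi_ref_deg: 80.0
  TA:
    F_max: 800.0
    l_opt: 0.06
    l_slack: 0.24
    v_max: 12.0
    delay: 0.02
    S0: 0.01
    attachments:
    - joint: ankle
      r: 0.028
      phi_max_deg: 80.0
      phi_ref_deg: 110.0
  GAS:
    F_max: 1500.0
    l_opt: 0.05
    l_slack: 0.4
    v_max: 12.0
    delay: 0.02
    S0: 0.01
    attachments:
    - joint: ankle
      r: -0.035
      phi_max_deg: 110.0
      phi_ref_deg: 80.0
    - joint: knee
      r: 0.035
      phi_max_deg: 140.0
      phi_ref_deg: 165.0
  VAS:
    F_max: 6000.0
    l_opt: 0.08
    l_slack: 0.23
    v_max: 12.0
    delay: 0.01
    S0: 0.01
    attachments:
    - joint: knee
      r: -0.036
      phi_max_deg: 165.0
      phi_ref_deg: 125.0
  HAM:
    F_max: 3000.0
    l_opt: 0.1
    l_slack: 0.31
    v_max: 12.0
    delay: 0.01
    S0: 0.01
    attachments:
    - joint: hip
      r: -0.056
      phi_max_deg: null
      phi_ref_deg: 155.0
    - joint: knee
      r: 0.035
      phi_max_deg: 180.0
      phi_ref_deg: 180.0
  GLU:
    F_max: 1500.0
    l_opt: 0.11
    l_slack: 0.13
    v_max: 12.0
    delay: 0.005
    S0: 0.01
    attachments:
    - joint: hip
      r: -0.05
      phi_max_deg: null
      phi_ref_deg: 150.0
  HFL:
    F_max: 2000.0
    l_opt: 0.11
    l_slack: 0.1
    v_max: 12.0
    delay: 0.005
    S0: 0.01
    attachments:
    - joint: hip
      r: 0.05
      phi_max_deg: null
      phi_ref_deg: 180.0
reflexes:
  G_SOL: 1.6552
  G_TA: 2.0
  l_off_TA: 0.71
  G_SOLTA: 0.3
  G_GAS: 2.2478
  G_VAS: 2.2921
  k_phi: 2.0
  phi_knee_off_deg: 175.0
  G_VAS_DS: 3.0851
  theta_ref: 0.105
  kp_trunk: 2.0
  kd_trunk: 0.8142
  c_GLU: 1.0057
  c_HAM: 1.0157
  c_HFL: 1.5
  k_DS_HFL: 1.1179
  k_DS_HAM: 0.4087
  G_HFL: 1.7318
  l_off_HFL: 0.5078
  G_HAMHFL: 8.0
  l_off_HAMHFL: 0.78
  k_lean: 4.1241
  G_GLU_sw: 0.3256
  G_HAM_sw: 0.6947
contact:
  k_vertical: 78500.0
  exponent: 1.0
  v_damping: 0.03
  mu_stiction: 0.9
  mu_sliding: 0.8
  k_horizontal: 7800.0
  d_horizontal: 300.0
  v_slide_ref: 0.01
  v_restick: 0.05
joint_limits:
  hip:
    lo_deg: 30.0
    hi_deg: 230.0
    stiffness: 300.0
    damping: 20.0
  knee:
    lo_deg: 45.0
    hi_deg: 175.0
    stiffness: 300.0
    damping: 20.0
  ankle:
    lo_deg: 65.0
    hi_deg: 130.0
    stiffness: 300.0
    damping: 20.0
failure:
  min_height_frac: 0.7
  max_lean_deg: 60.0
initial_state:
  hip_xy:
  - 0.0
  - 1.073
  lean_deg: 6.0
  left:
    hip_deg: 170.0
    knee_deg: 175.0
    ankle_deg: 90.0
  right:
    hip_deg: 153.33
    knee_deg: 113.61
    ankle_deg: 85.0
  forward_velocity: 1.1303
  joint_rates_deg:
    right:
      hip: -93.57
      knee: 83.91
  activation_left:
    VAS: 0.107
    SOL: 0.359
    GLU: 0.153
    HAM: 0.153
    GAS: 0.1
  activation_right:
    HFL: 0.575
    TA: 0.2
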