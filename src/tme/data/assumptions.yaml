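# Assumption relations closing the steady-state parameter estimation.
#
# The 17 steady-state equations alone cannot determine the 57 unknown rates,
# so each equation block carries linear relations between its parameters:
# production or death channels are assumed comparably effective when each
# rate is weighted by the scale maximum of its interacting variable (factors
# "max:X"; "ss:X" selects the steady-state value instead when the estimator
# runs in steady-state context mode).  Every relation reads
#
#     scale * sum(lhs)  ==  sum(rhs)
#
# and re-estimating with a changed scale probes how strongly the model
# leans on that assumption.  The cancer-death and macrophage-activation
# splits are the relations the downstream scaling experiments target; the
# remainder complete the system in the same style.
relations:
  # --- helper T cells ----------------------------------------------------
  - label: th_act_d_vs_h
    lhs: [{param: lambda_ThD, factors: ["max:D"]}]
    rhs: [{param: lambda_ThH, factors: ["max:H"]}]
  - label: th_act_d_vs_il12
    lhs: [{param: lambda_ThD, factors: ["max:D"]}]
    rhs: [{param: lambda_ThIL12, factors: ["max:IL12"]}]
  - label: th_act_d_vs_e
    lhs: [{param: lambda_ThD, factors: ["max:D"]}]
    rhs: [{param: lambda_ThE, factors: ["max:E"]}]
  - label: th_inh_treg
    lhs: [{param: delta_ThTr, factors: ["max:Tr"]}]
    rhs: [{param: delta_Th}]
  - label: th_inh_il10
    lhs: [{param: delta_ThIL10, factors: ["max:IL10"]}]
    rhs: [{param: delta_Th}]
  # --- cytotoxic cells ----------------------------------------------------
  - label: tc_act_d_vs_e
    lhs: [{param: lambda_TcD, factors: ["max:D"]}]
    rhs: [{param: lambda_TcE, factors: ["max:E"]}]
  - label: tc_act_d_vs_il12
    lhs: [{param: lambda_TcD, factors: ["max:D"]}]
    rhs: [{param: lambda_TcIL12, factors: ["max:IL12"]}]
  - label: tc_inh_treg
    lhs: [{param: delta_TcTr, factors: ["max:Tr"]}]
    rhs: [{param: delta_Tc}]
  - label: tc_inh_il10
    lhs: [{param: delta_TcIL10, factors: ["max:IL10"]}]
    rhs: [{param: delta_Tc}]
  # --- regulatory T cells -------------------------------------------------
  - label: tr_act_d_vs_e
    lhs: [{param: lambda_TrD, factors: ["max:D"]}]
    rhs: [{param: lambda_TrE, factors: ["max:E"]}]
  # --- dendritic cells ----------------------------------------------------
  - label: dc_act_c_vs_h
    lhs: [{param: lambda_DC, factors: ["max:C"]}]
    rhs: [{param: lambda_DH, factors: ["max:H"]}]
  - label: dc_act_c_vs_e
    lhs: [{param: lambda_DC, factors: ["max:C"]}]
    rhs: [{param: lambda_DE, factors: ["max:E"]}]
  - label: dc_death_by_cancer
    lhs: [{param: delta_DC, factors: ["max:C"]}]
    rhs: [{param: delta_D}]
  - label: dcn_natural_death
    lhs: [{param: delta_DN}]
    rhs: [{param: delta_D}]
  # --- macrophages --------------------------------------------------------
  - label: m_act_ifng_vs_il10
    lhs: [{param: lambda_MIg, factors: ["max:Ig"]}]
    rhs: [{param: lambda_MIL10, factors: ["max:IL10"]}]
  - label: m_act_estrogen_vs_il10
    lhs: [{param: lambda_ME, factors: ["max:E"]}]
    rhs: [{param: lambda_MIL10, factors: ["max:IL10"]}]
  - label: m_act_th_vs_il10
    lhs: [{param: lambda_MTh, factors: ["max:Th"]}]
    rhs: [{param: lambda_MIL10, factors: ["max:IL10"]}]
  - label: m_act_il12_vs_il10
    lhs: [{param: lambda_MIL12, factors: ["max:IL12"]}]
    rhs: [{param: lambda_MIL10, factors: ["max:IL10"]}]
  - label: mn_natural_death
    lhs: [{param: delta_MN}]
    rhs: [{param: delta_M}]
  # --- cancer cells -------------------------------------------------------
  - label: kill_split_tc_vs_ifng
    lhs: [{param: delta_CTc, factors: ["max:Tc"]}]
    rhs: [{param: delta_CIg, coeff: 6.0, factors: ["max:Ig"]}]
  - label: death_split_natural_vs_ifng
    lhs: [{param: delta_C}]
    rhs: [{param: delta_CIg, coeff: 6.0, factors: ["max:Ig"]}]
  - label: growth_split_adipocyte_vs_il6
    lhs: [{param: lambda_CA, coeff: 2.0, factors: ["max:A"]}]
    rhs: [{param: lambda_CIL6, factors: ["max:IL6"]}]
  - label: c_growth_intrinsic
    lhs: [{param: lambda_C}]
    rhs: [{param: lambda_CIL6, factors: ["max:IL6"]}]
  # --- HMGB1 ---------------------------------------------------------------
  - label: h_src_d_vs_n
    lhs: [{param: lambda_HD, factors: ["max:D"]}]
    rhs: [{param: lambda_HN, factors: ["max:N"]}]
  - label: h_src_d_vs_m
    lhs: [{param: lambda_HD, factors: ["max:D"]}]
    rhs: [{param: lambda_HM, factors: ["max:M"]}]
  - label: h_src_d_vs_tc
    lhs: [{param: lambda_HD, factors: ["max:D"]}]
    rhs: [{param: lambda_HTc, factors: ["max:Tc"]}]
  - label: h_src_d_vs_c
    lhs: [{param: lambda_HD, factors: ["max:D"]}]
    rhs: [{param: lambda_HC, factors: ["max:C"]}]
  # --- IL-12 ---------------------------------------------------------------
  - label: il12_src_m_vs_d
    lhs: [{param: lambda_IL12M, factors: ["max:M"]}]
    rhs: [{param: lambda_IL12D, factors: ["max:D"]}]
  - label: il12_src_m_vs_th
    lhs: [{param: lambda_IL12M, factors: ["max:M"]}]
    rhs: [{param: lambda_IL12Th, factors: ["max:Th"]}]
  - label: il12_src_m_vs_tc
    lhs: [{param: lambda_IL12M, factors: ["max:M"]}]
    rhs: [{param: lambda_IL12Tc, factors: ["max:Tc"]}]
  # --- IL-10 ---------------------------------------------------------------
  - label: il10_src_m_vs_d
    lhs: [{param: lambda_IL10M, factors: ["max:M"]}]
    rhs: [{param: lambda_IL10D, factors: ["max:D"]}]
  - label: il10_src_m_vs_tr
    lhs: [{param: lambda_IL10M, factors: ["max:M"]}]
    rhs: [{param: lambda_IL10Tr, factors: ["max:Tr"]}]
  - label: il10_src_m_vs_th
    lhs: [{param: lambda_IL10M, factors: ["max:M"]}]
    rhs: [{param: lambda_IL10Th, factors: ["max:Th"]}]
  - label: il10_src_m_vs_tc
    lhs: [{param: lambda_IL10M, factors: ["max:M"]}]
    rhs: [{param: lambda_IL10Tc, factors: ["max:Tc"]}]
  - label: il10_src_m_vs_c
    lhs: [{param: lambda_IL10M, factors: ["max:M"]}]
    rhs: [{param: lambda_IL10C, factors: ["max:C"]}]
  # --- estrogen ------------------------------------------------------------
  - label: e_src_a_vs_self
    lhs: [{param: lambda_EA, factors: ["max:A"]}]
    rhs: [{param: lambda_E, factors: ["max:E"]}]
  # --- IFN-gamma -----------------------------------------------------------
  - label: ig_src_tc_vs_th
    lhs: [{param: lambda_IgTc, factors: ["max:Tc"]}]
    rhs: [{param: lambda_IgTh, factors: ["max:Th"]}]
  - label: ig_src_tc_vs_d
    lhs: [{param: lambda_IgTc, factors: ["max:Tc"]}]
    rhs: [{param: lambda_IgD, factors: ["max:E", "max:D"]}]
  # --- IL-6 ----------------------------------------------------------------
  - label: il6_src_a_vs_m
    lhs: [{param: lambda_IL6A, factors: ["max:A"]}]
    rhs: [{param: lambda_IL6M, factors: ["max:M"]}]
  - label: il6_src_a_vs_d
    lhs: [{param: lambda_IL6A, factors: ["max:A"]}]
    rhs: [{param: lambda_IL6D, factors: ["max:D"]}]
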