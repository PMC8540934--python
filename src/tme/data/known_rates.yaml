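# Death/clearance rates fixed from measured cell and molecule half-lives
# (rate = ln 2 / half-life, in 1/day).  These 13 rates are inputs to the
# steady-state parameter estimation, not estimated quantities.
#
# Half-lives are representative literature values for the tumor context:
# naive T cells are long-lived; effector and regulatory T cells and
# activated dendritic cells turn over in days; macrophages in weeks;
# tumor-associated adipocytes remodel on a months scale; extracellular
# HMGB1, estrogen and the cytokines clear within hours.
rates:
  delta_TN:   {half_life_days: 365.0, source: "naive T-cell lifespan ~1 y"}
  delta_Th:   {half_life_days: 3.0,   source: "activated CD4+ T cell ~3 d"}
  delta_Tc:   {half_life_days: 1.7,   source: "effector CD8+/NK ~41 h"}
  delta_Tr:   {half_life_days: 2.0,   source: "regulatory T cell ~2 d"}
  delta_D:    {half_life_days: 2.5,   source: "activated dendritic cell ~2.5 d"}
  delta_M:    {half_life_days: 30.0,  source: "tissue macrophage ~1 month"}
  delta_A:    {half_life_days: 180.0, source: "tumor-associated adipocyte remodelling ~6 months"}
  delta_H:    {half_life_days: 0.083, source: "extracellular HMGB1 ~2 h"}
  delta_E:    {half_life_days: 0.083, source: "estradiol ~2 h"}
  delta_IL6:  {half_life_days: 0.042, source: "IL-6 ~1 h"}
  delta_IL10: {half_life_days: 0.125, source: "IL-10 ~3 h"}
  delta_IL12: {half_life_days: 0.333, source: "IL-12 ~8 h"}
  delta_Ig:   {half_life_days: 0.167, source: "IFN-gamma ~4 h"}
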