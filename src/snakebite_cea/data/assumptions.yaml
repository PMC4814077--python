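# Cross-country model constants and the per-patient cost bundle (USD).
# Costs are stored to the cent exactly as reported; no currency-year
# adjustment is applied.
global_assumptions:
  p_ear_mort: 0.01        # probability of death given an early adverse reaction
  p_disabl: 0.03          # probability of amputation among survivors
  dw_amputation: 0.102
  discount_rate: 0.03     # annual, applied to health outcomes only
  dw_blindness: 0.552
  p_blindness: 0.0001
  dw_ptsd: 0.105
  p_ptsd: 0.20
  adrenaline_x: 0.40      # multiplicative reduction of EAR risk with premedication
cost_inputs:
  c_antivenom: 153.0
  c_20wbct: 3.125         # ten 20WBCT tests over 7 days
  c_adv_reaction: 1.875   # incurred only in EAR branches
  c_supp_care: 18.75
  c_feed_transp: 43.75
  c_refrg_transp: 18.75
  c_no_antivenom: 0.0     # comparator arm; 65.63 in the basic-care scenario
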