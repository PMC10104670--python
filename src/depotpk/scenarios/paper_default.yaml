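# Calibrated default scenario: a single 2 µg intra-articular dose of
# 6.5 µm PLGA-ATRA microparticles at the printed ≈1.2 wt% composition.
# k_elim = ln 2 / 0.75 h (45 min serum half-life of ATRA); k_exchange is an
# order-of-magnitude synovium->blood permeability estimate.
formulation:
  polymer_mass_mg: 100.0
  drug_feed_mass_mg: 2.0
  encapsulation_efficiency: 0.624
  drug_molar_mass: 300.44
  size_class_label: "6.5 um"
dose:
  mp_mass_ug: 2.0
  vehicle_volume_ul: 20.0
  synovial_volume_ul: 20.0
pk:
  V_syn_ul: 20.0
  V_dist_ml: 11.0
  k_exchange_per_h: 0.1
  k_elim_per_h: 0.9241962407465937   # ln 2 / 0.75
  loading: 0.012                     # the printed 1.2 wt% composition
release:
  size_class: "6.5 um"
  shape: piecewise_linear
output:
  t_end_h: 672.0
  syn_threshold_nM: 6.0
  window_days: [1.0, 28.0]
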