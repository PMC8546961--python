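# Central kinetic parameter values for the three G6PDH isozymes of
# Pseudomonas putida KT2440, as determined by global fitting of initial-rate
# data to a rapid-equilibrium random-ordered bi-bi mechanism.
#
# Units: kcat in 1/s, all dissociation/inhibition constants in uM.
#   km_cofactor : dissociation of the oxidized cofactor from the ternary complex
#   ki_cofactor : dissociation of the oxidized cofactor from free enzyme
#   km_g6p      : dissociation of G6P from the enzyme-cofactor complex
#   kic_product : competitive inhibition constant of the reduced cofactor
#   kis_cofactor: substrate-inhibition constant (only where observed)
enzymes:
  G6PDH-A:
    nad:
      kcat: 277.0
      km_cofactor: 127.0
      ki_cofactor: 1148.0
      km_g6p: 1137.0
      kic_product: 480.0
    nadp:
      kcat: 102.0
      km_cofactor: 14.0
      ki_cofactor: 111.0
      km_g6p: 946.0
      kic_product: 18.0
  G6PDH-B:
    nad:
      kcat: 120.0
      km_cofactor: 151.0
      ki_cofactor: 301.0
      km_g6p: 291.0
      kic_product: 337.0
      kis_cofactor: 1390.0
    nadp:
      kcat: 113.0
      km_cofactor: 165.0
      ki_cofactor: 790.0
      km_g6p: 190.0
      kic_product: 38.0
  G6PDH-C:
    nad:
      kcat: 0.77
      km_cofactor: 9500.0
      ki_cofactor: 5800.0
      km_g6p: 2030.0
      kic_product: 23.0e+6
    nadp:
      kcat: 0.54
      km_cofactor: 3.2
      ki_cofactor: 9.2
      km_g6p: 944.0
      kic_product: 775.0
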