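# Reference parameterizations of the two-codon model.
#
# Shared values: 2500 total tRNAs, 500 ribosomes, 100 transcripts of
# 300 codons, elongation constant 0.02 per charged tRNA per bound
# ribosome per second.  k_charge and k_bind_eff are the closed-form
# calibration of the symmetric baseline to an 88% charged-tRNA fraction
# and an 88% active-ribosome fraction:
#   k_charge  = 484/15    = 32.266666666666666   (1/s)
#   k_bind_eff = 121/22500 = 5.377777777777778e-3 (per molecule per site per s)
# The three sets differ only in the preferred / non-preferred tRNA split.
baseline:
  T1_tot: 1250
  T2_tot: 1250
  R_tot: 500
  N: 100
  L: 300
  k_charge: 32.266666666666666
  k_speed: 0.02
  k_bind_eff: 5.377777777777778e-3
  f_op: 0.5
ratio07:
  T1_tot: 1750
  T2_tot: 750
  R_tot: 500
  N: 100
  L: 300
  k_charge: 32.266666666666666
  k_speed: 0.02
  k_bind_eff: 5.377777777777778e-3
  f_op: 0.5
ratio09:
  T1_tot: 2250
  T2_tot: 250
  R_tot: 500
  N: 100
  L: 300
  k_charge: 32.266666666666666
  k_speed: 0.02
  k_bind_eff: 5.377777777777778e-3
  f_op: 0.5
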