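# Named parameter presets.
#
# "reference": final population estimates of the rat oxaliplatin neuropathy
# study (two-compartment PK; acute acetone-test turnover model; chronic von
# Frey transit-chain model). omega values are percent CV of exponential
# inter-individual variability; sigma_*_prop are proportional residual
# fractions; sigma_chronic_add is an additive residual SD in grams.
reference:
  pk:
    V: 357.8      # mL/kg
    ke: 3.4       # 1/h
    k12: 2.6      # 1/h
    k21: 1.1      # 1/h
  acute:
    kin_acute: 0.004    # times/day
    kout_acute: 0.06    # 1/day
    Emax_acute: 10.1    # times/day
    EC50_acute: 0.36    # ug/mL
    x0_acute: 3.1       # times (fixed)
    k_handling: 0.08    # 1/day (fixed)
    gamma_acute: 6      # (fixed)
  chronic:
    kin_chronic: 2.7    # g/day
    Emax_chronic: 168.0
    EC50_chronic: 0.43  # ug/mL
    x0_chronic: 8       # g (fixed)
    n_transit: 5        # (fixed)
    gamma_chronic: 4    # (fixed)
  omega:
    V: 42.4
    ke: 40.6
    k12: 54.3
    k21: 91.0
    kin_chronic: 25.2
    EC50_chronic: 28.2
  sigma_pk_prop: 0.219
  sigma_acute_prop: 0.321
  sigma_chronic_add: 1.3
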