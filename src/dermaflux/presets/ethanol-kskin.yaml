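# Ethanol through dry stratum corneum — permeability parameterisation.
# D value used in published skin-permeability chains; C0 corresponds to a
# blood alcohol concentration of 100 mg/dL (MW 46.07 g/mol).
skin:
  D_cm2_per_s: 5.0e-10
  L_cm: 1.5e-3
  C0_mol_per_cm3: 2.1706099413935314e-05
sensor:
  kind: robin
  alpha_cm_per_s: 2.45e-7
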