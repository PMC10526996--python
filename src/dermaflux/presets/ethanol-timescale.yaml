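# Ethanol through dry stratum corneum — response-timescale parameterisation.
# D value used in published response-time estimates; same slab thickness and
# blood concentration as the permeability preset.
skin:
  D_cm2_per_s: 3.0e-11
  L_cm: 1.5e-3
  C0_mol_per_cm3: 2.1706099413935314e-05
sensor:
  kind: concentration
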