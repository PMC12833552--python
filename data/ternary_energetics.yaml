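# Thermodynamic inputs of the two molecular-glue ternary complexes,
# consumed as printed numbers by the thermodynamics stage.
#
# kd_table rows: label, Kd (mol/L), Kd SD (mol/L)
#   experimentally determined dissociation constants at 25 C for the
#   ternary complexes (target protein binding to the preformed
#   effector-glue binary complex).
# energy_components rows: label, ternary dG, ternary SD, binary dG, binary SD
#   MM/GBSA binding free energies (kcal/mol, mean +- SD over three
#   replicas): the ternary complex and the target-protein/glue binary
#   complex whose difference defines the cooperative free energy.
kd_table:
  - [FKBP12-rapamycin-FRAP, 12.0e-9, 0.8e-9]
  - [FKBP12-WDB002-CEP250, 41.2e-9, 5.7e-9]
energy_components:
  - [FKBP12-rapamycin+FRAP, -61.15, 5.30, -34.82, 0.70]
  - [FKBP12-WDB002+CEP250, -63.34, 1.66, -20.82, 0.70]
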