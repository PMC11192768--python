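# Reference single-cell staining protocol: bacteria + intercalating dye.
# Three of the six reservoirs are loaded; incubation is 20 minutes per the
# dye's standard staining procedure.
inlet_loads:
  - {reservoir: R1, reagent: ecoli_pbs, volume_ul: 2.0}
  - {reservoir: R2, reagent: sybr_gold, volume_ul: 2.0}
  - {reservoir: R3, reagent: pbs, volume_ul: 5.0}
incubation_ms: 1200000   # 20 min
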