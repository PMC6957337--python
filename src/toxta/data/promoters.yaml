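crp_s_basal: 50.0
crp_s_induction:
  0: 1.0
  10: 1.5
  30: 10.0
  100: 10.0
crp_s_genotype_modifier:
  wildtype: 1.0
  dtoxA: 1.0
  dtoxT: 1.0
  dtoxTA: 0.3811
  dcrp: 1.0
  dsxy: 1.0
induction_blocked:
- dcrp
- dsxy
p2_rate:
  wildtype: 2.0
  dtoxT: 2.0
  dcrp: 2.0
  dsxy: 2.0
  dtoxA: 508.78
  dtoxTA: 0.7621
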