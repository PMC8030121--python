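# Variants dropped from the candidate panels before score construction.
# hwe_failure: departure from Hardy-Weinberg equilibrium at Bonferroni-
#   corrected P < 0.05 in one of the genotyped cohorts.
# bmi_primary_effect: association with the outcome mediated primarily
#   through adiposity rather than a direct glycaemic effect.
exclusions:
  fpg:
    - rsid: rs10885122
      reason: hwe_failure
      note: ADRA2A locus; HWE departure in the case-control cohort
  t2d:
    - rsid: rs8042680
      reason: hwe_failure
      note: PRC1 locus; HWE departure in the case-control cohort
    - rsid: rs1470579
      reason: hwe_failure
      note: IGF2BP2 locus; HWE departure in the representative cohort
    - rsid: rs11642841
      reason: bmi_primary_effect
      note: FTO locus; primary effect on BMI
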