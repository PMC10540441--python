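# Normative reference statistics for the 17 gait parameters.
# Derived from a reference group of 19 healthy adults (110 trials of the
# 10-m out-and-back walking test, two trials per visit).
# z_coefficient: +1 if an increase of the parameter is beneficial,
# -1 if it is pathological.
provenance: healthy adult reference group (n=19, 110 trials)
parameters:
  V:        {mean: 1.22,  sd: 0.20, z_coefficient: 1}
  StrT:     {mean: 1.10,  sd: 0.09, z_coefficient: -1}
  UtrT:     {mean: 2.62,  sd: 0.75, z_coefficient: -1}
  LDLJ_A:   {mean: -8.07, sd: 0.35, z_coefficient: 1}
  SPARC_G:  {mean: -5.37, sd: 0.84, z_coefficient: -1}
  CV_StrT:  {mean: 2.34,  sd: 0.97, z_coefficient: -1}
  CV_dstT:  {mean: 5.63,  sd: 2.07, z_coefficient: -1}
  P1_aCC:   {mean: 0.82,  sd: 0.10, z_coefficient: 1}
  P2_aCC:   {mean: 0.82,  sd: 0.10, z_coefficient: 1}
  SteL:     {mean: 0.68,  sd: 0.08, z_coefficient: 1}
  RMS_aML:  {mean: 1.28,  sd: 0.33, z_coefficient: -1}
  iHR_aAP:  {mean: 95.48, sd: 2.13, z_coefficient: 1}
  iHR_aCC:  {mean: 94.88, sd: 3.10, z_coefficient: 1}
  iHR_aML:  {mean: 86.77, sd: 6.32, z_coefficient: 1}
  P1P2_aCC: {mean: 0.96,  sd: 0.04, z_coefficient: 1}
  swTr:     {mean: 0.96,  sd: 0.03, z_coefficient: 1}
  dstT:     {mean: 23.34, sd: 3.50, z_coefficient: -1}
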