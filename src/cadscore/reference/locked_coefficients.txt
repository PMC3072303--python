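# SYNTHETIC reference coefficients — ridge fit on the packaged
# simulated cohort (n=640, seed=17); non-clinical.
# Regenerate with scripts/make_reference_coefficients.py
# cadscore locked-model coefficients
female_age_hinge_slope: 0.09286186363058103
intercept: 0.05383071887326571
knot: 60.0
male_age_slope: 0.05624686310710415
sex_coefficient: -8.079077354818278
term_weights:
  T1:
    F: -1.1803718781938441
    M: 1.2840193750819708
  T2:
    F: -0.555257186776269
    M: 0.19913565223005103
  T3:
    F: -0.13466476110262207
    M: -0.3446627800332265
  T4:
    F: 0.19843535809953214
    M: 0.27444933927179455
  T5:
    F: 0.21863782755074077
    M: 0.284216944300461
  T6:
    F: 0.07297393719647259
    M: 0.07297393719647259
transform:
- 1.0
- 0.0
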