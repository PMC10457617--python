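# Noninvasive screening-test performance assumptions and intervals.
#
# Sensitivities are per-person, by the most advanced lesion present:
# adenoma <10 mm (nonadvanced), adenoma >=10 mm (advanced), preclinical CRC.
# Stool tests use published trial values; the blood scenarios S1-S5 model a
# hypothetical triennial blood test at the CMS minimum thresholds (74% CRC
# sensitivity, 90% specificity) with adenoma sensitivity varied from 10%
# (the false-positive floor) to 20%.  S2 and S4 derive the nonadvanced value
# from the advanced one by the half-rule (half the advanced sensitivity in
# excess of the accidental-finding floor 1 - specificity).

tests:
  mt_sdna:   {sens_nonadvanced: 0.15,  sens_advanced: 0.42, sens_crc: 0.94, specificity: 0.91, interval_years: 3}
  fit:       {sens_nonadvanced: 0.07,  sens_advanced: 0.22, sens_crc: 0.74, specificity: 0.97, interval_years: 1}
  fobt:      {sens_nonadvanced: 0.05,  sens_advanced: 0.11, sens_crc: 0.68, specificity: 0.97, interval_years: 1}
  blood_s1:  {sens_nonadvanced: 0.10,  sens_advanced: 0.10, sens_crc: 0.74, specificity: 0.90, interval_years: 3}
  blood_s2:  {sens_nonadvanced: 0.125, sens_advanced: 0.15, sens_crc: 0.74, specificity: 0.90, interval_years: 3}
  blood_s3:  {sens_nonadvanced: 0.15,  sens_advanced: 0.15, sens_crc: 0.74, specificity: 0.90, interval_years: 3}
  blood_s4:  {sens_nonadvanced: 0.15,  sens_advanced: 0.20, sens_crc: 0.74, specificity: 0.90, interval_years: 3}
  blood_s5:  {sens_nonadvanced: 0.20,  sens_advanced: 0.20, sens_crc: 0.74, specificity: 0.90, interval_years: 3}

# observed real-world per-round completion rates for the stool tests
real_world_adherence: {mt_sdna: 0.656, fit: 0.426, fobt: 0.344}
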