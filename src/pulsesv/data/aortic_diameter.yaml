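# Linear ascending-aortic diameter model used for body-size scaling of
# the arterial tree:
#
#   diameter_cm = intercept[gender] + age_slope * age_years + bsa_slope * BSA_m2
#
# with BSA from the Du Bois formula. The coefficients are package
# defaults chosen to reproduce typical adult aortic-root calibres
# (~2.8-3.0 cm) and their published age/gender/body-size trends; the
# subject scaling uses only the RATIO of the subject's predicted
# diameter to the reference subject's, so the intercepts' absolute level
# cancels. All values are editable.
schema_version: 1
bsa_formula: dubois
intercept: {M: 1.60, F: 1.52}
age_slope: 0.008      # cm per year
bsa_slope: 0.45       # cm per m^2
reference:
  age: 45.0
  gender: M
  weight: 77.0
  height: 180.0
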