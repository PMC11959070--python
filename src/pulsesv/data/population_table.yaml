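# Age/gender-stratified population distributions (mean, SD) of the 1-D
# model input parameters, as compiled from published reference data.
# Units: height cm, weight kg, heart_rate bpm, aortic_distensibility
# 10^-3/mmHg, tpr mmHg*s/mL, map mmHg.
#
# floors: positivity floors used by the truncated-Gaussian sampler;
# draws are redrawn until they fall in [max(mean-3SD, floor), mean+3SD].
schema_version: 1
age_groups: ["20-29", "30-39", "40-49", "50-59", "60-69", ">70"]
age_midpoints: {"20-29": 24.5, "30-39": 34.5, "40-49": 44.5, "50-59": 54.5, "60-69": 64.5, ">70": 75.0}
floors:
  height: 120.0
  weight: 35.0
  heart_rate: 35.0
  aortic_distensibility: 0.3
  tpr: 0.5
  map: 55.0
parameters:
  height:
    M: {"20-29": [175, 15], "30-39": [175, 15], "40-49": [175, 15], "50-59": [175, 15], "60-69": [175, 15], ">70": [175, 15]}
    F: {"20-29": [175, 15], "30-39": [175, 15], "40-49": [175, 15], "50-59": [175, 15], "60-69": [175, 15], ">70": [175, 15]}
  weight:
    M: {"20-29": [77, 10], "30-39": [79, 10], "40-49": [86, 9], "50-59": [77, 9], "60-69": [79, 5], ">70": [75, 9]}
    F: {"20-29": [61, 7], "30-39": [66, 8], "40-49": [65, 11], "50-59": [62, 6], "60-69": [69, 15], ">70": [62, 9]}
  heart_rate:
    M: {"20-29": [64, 11], "30-39": [63, 9], "40-49": [66, 11], "50-59": [63, 13], "60-69": [65, 13], ">70": [72, 13]}
    F: {"20-29": [69, 13], "30-39": [59, 8], "40-49": [67, 12], "50-59": [67, 9], "60-69": [67, 8], ">70": [67, 13]}
  aortic_distensibility:
    M: {"20-29": [7.8, 2.5], "30-39": [5.3, 1.8], "40-49": [3.8, 1.3], "50-59": [3.3, 1.6], "60-69": [1.8, 1.3], ">70": [1.3, 0.9]}
    F: {"20-29": [8.9, 2.5], "30-39": [5.9, 2.6], "40-49": [4.0, 1.6], "50-59": [3.1, 1.8], "60-69": [1.2, 0.8], ">70": [1.1, 0.8]}
  tpr:
    M: {"20-29": [1.15, 0.26], "30-39": [1.2, 0.27], "40-49": [1.28, 0.29], "50-59": [1.34, 0.31], "60-69": [1.41, 0.33], ">70": [1.49, 0.34]}
    F: {"20-29": [1.15, 0.26], "30-39": [1.2, 0.27], "40-49": [1.28, 0.29], "50-59": [1.34, 0.31], "60-69": [1.41, 0.33], ">70": [1.49, 0.34]}
  map:
    M: {"20-29": [89, 8], "30-39": [92, 8], "40-49": [95, 7], "50-59": [95, 7], "60-69": [94, 7], ">70": [93, 7]}
    F: {"20-29": [86, 8], "30-39": [88, 9], "40-49": [90, 9], "50-59": [93, 8], "60-69": [93, 8], ">70": [92, 8]}
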