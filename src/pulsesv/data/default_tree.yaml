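# Reduced systemic arterial tree (schema version 1).
#
# Eight segments covering the measurement paths the stroke-volume
# pipeline needs: aortic root -> thoracic/abdominal aorta -> iliac ->
# femoral, plus common-carotid and subclavian/brachial branches. Every
# leaf is closed by a three-element Windkessel (r1/r2 in mmHg*s/mL,
# compliance in mL/mmHg). Lengths/diameters in cm, distensibility in
# 10^-3/mmHg at the reference pressure. The reference state corresponds
# to a 180 cm adult; terminal resistances give a total peripheral
# resistance of ~1.02 mmHg*s/mL so the reference cardiac output of
# 5.5 L/min yields a physiological mean pressure.
schema_version: 1
blood:
  density: 1050.0
  viscosity: 0.004
reference:
  height_cm: 180.0
  aortic_distensibility: 5.0
  pressure_mmhg: 90.0
root: aorta_ascending
segments:
  - {name: aorta_ascending,     length: 7.0,  din: 3.0, dout: 2.7, distensibility: 5.0}
  - {name: carotid,             length: 18.0, din: 0.9, dout: 0.7, distensibility: 4.0}
  - {name: subclavian_brachial, length: 45.0, din: 1.1, dout: 0.5, distensibility: 3.0}
  - {name: aorta_thoracic,      length: 17.0, din: 2.5, dout: 2.0, distensibility: 5.0}
  - {name: visceral,            length: 6.0,  din: 1.2, dout: 0.9, distensibility: 3.5}
  - {name: aorta_abdominal,     length: 13.0, din: 1.8, dout: 1.5, distensibility: 4.5}
  - {name: iliac_femoral,       length: 42.0, din: 1.0, dout: 0.6, distensibility: 2.8}
  - {name: iliac_contralateral, length: 10.0, din: 1.0, dout: 0.8, distensibility: 2.8}
topology:
  aorta_ascending: [carotid, subclavian_brachial, aorta_thoracic]
  aorta_thoracic: [visceral, aorta_abdominal]
  aorta_abdominal: [iliac_femoral, iliac_contralateral]
terminals:
  carotid:             {r1: 1.00, r2: 4.67, compliance: 0.063, pout: 0.0}
  subclavian_brachial: {r1: 2.60, r2: 8.73, compliance: 0.032, pout: 0.0}
  visceral:            {r1: 0.74, r2: 1.53, compliance: 0.158, pout: 0.0}
  iliac_femoral:       {r1: 1.88, r2: 4.50, compliance: 0.056, pout: 0.0}
  iliac_contralateral: {r1: 1.06, r2: 7.44, compliance: 0.042, pout: 0.0}
sites:
  aortic_root:   {segment: aorta_ascending, position: 0.0}
  carotid:       {segment: carotid, position: 0.85}
  left_brachial: {segment: subclavian_brachial, position: 0.9}
  femoral:       {segment: iliac_femoral, position: 0.5}
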