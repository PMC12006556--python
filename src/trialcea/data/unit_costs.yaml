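# Unit costs of sampling and community care, UK NHS perspective,
# 2021/22 price year (PSSRU and National Schedule of NHS Costs).
price_year: "2021/22"
samples:
  tissue: 20.0
  swab: 12.0
  bone: 124.0
contacts:
  gp: 38.0
  practice_nurse: 13.0   # 52/hour with qualifications x 15.5 min
  district_nurse: 54.0
  foot_clinic: 93.0
  outpatient: 183.0
  a_and_e: 144.0
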