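id: v_d_01_5
age: 66
sex: male
modeled_disease: d_01
presenting:
  s_04: present
open_facts:
  s_03: present
direct_facts:
  s_01: present
judge_range:
  min: ambulance
  max: ambulance
annual_incidence: 0.0008542704033115318
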