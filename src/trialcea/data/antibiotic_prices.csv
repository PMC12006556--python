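drug,form,unit_cost
amoxicillin,500 mg capsule,0.21
benzylpenicillin,600 mg vial,2.89
ceftazidime,2 g vial,16.43
ceftriaxone,250 mg vial,2.37
ceftriaxone,1 g vial,8.61
ceftriaxone,2 g vial,19.00
clindamycin,300 mg capsule,1.03
clindamycin,150 mg/mL ampoule,8.77
clarithromycin,500 mg tablet,0.65
clarithromycin,500 mg vial,10.85
ciprofloxacin,500 mg tablet,0.25
co-amoxiclav,500 mg/125 mg tablet,0.39
co-amoxiclav,500 mg/100 mg vial,1.30
co-trimoxazole,160 mg/800 mg tablet,0.25
doxycycline,100 mg capsule,0.16
ertapenem,1 g vial,31.65
erythromycin,500 mg tablet,0.45
erythromycin,1 g vial,22.46
flucloxacillin,500 mg capsule,0.16
flucloxacillin,500 mg vial,9.66
sodium fusidate,500 mg vial,21.95
gentamicin,40 mg/mL vial,1.38
linezolid,600 mg capsule,35.48
meropenem,500 mg vial,9.87
metronidazole,400 mg tablet,0.20
metronidazole,5 mg/mL infusion bag,3.49
phenoxymethylpenicillin,250 mg tablet,0.12
piperacillin-tazobactam,4 g/500 mg vial,12.18
rifampicin,600 mg capsule,9.20
teicoplanin,200 mg vial,6.55
tigecycline,50 mg vial,29.08
trimethoprim,200 mg tablet,0.27
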