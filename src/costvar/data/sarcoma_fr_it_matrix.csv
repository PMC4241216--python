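object,Q biopsies,Q hospital days,Q imaging,Q external consultations,Q transfusions,Q radiotherapy sessions,Q radiotherapy preparation,Q chemotherapy drugs,C biopsies,C hospital days,C imaging,C external consultations,C transfusions,C radiotherapy sessions,C radiotherapy preparation,C chemotherapy drugs
Diagnosis France,1.34,1.29,3.66,0.76,0,0,0,0,59.5,918.3,76.34,90,0,0,0,0
Diagnosis Italy,2.04,5.4,4.61,1.19,0,0,0,0,41.63,602,76.24,47.45,0,0,0,0
Surgery France,0,13.38,1.98,0,0.8,0,0,0,0,918.3,75.59,0,199.6,0,0,0
Surgery Italy,0,10.53,2.37,0,1.72,0,0,0,0,602,76.24,0,26.3,0,0,0
Chemotherapy France,0,20.54,5.29,0,2.92,0,0,2.88,0,918.3,98.75,0,199.6,0,0,2.22
Chemotherapy Italy,0,18.36,8.06,0,1.52,0,0,2.03,0,602,67.16,0,26.3,0,0,2.98
Radiotherapy France,0,1.08,0,0,0,26.44,1,0,0,918.3,0,0,0,137,439,0
Radiotherapy Italy,0,11,0,0,0,19.87,1,0,0,602,0,0,0,150,871.8,0
Follow-up without relapse France,0,0.38,3.28,3.41,0,0,0,0.05,0,918.3,66.69,90,0,0,0,0.04
Follow-up without relapse Italy,0,1.01,5.29,4.01,0,0.02,0.01,0,0,602,76.24,47.45,0,150,871.8,0
Follow-up with relapse France,0,7.47,2.53,5.18,0,2.47,0.13,1.53,0,918.3,75.59,90,0,137,439,3.49
Follow-up with relapse Italy,0,20,11.41,5.06,0,0.26,0.04,0.47,0,602,76.24,47.45,0,150,871.8,0.5
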