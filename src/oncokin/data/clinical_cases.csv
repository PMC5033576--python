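case_id,histology,V0_mm3,V1_mm3,reduction_printed_pct,interval_cts_days,interval_ct1_to_onset_days,CKR_B
1,SCC,100264,46776,53.35,47,5,0.2
2,SCC,568264,168048,70.43,46,4,0.2
3,SCC,101216,26336,73.98,45,4,0.2
4,SCC,41376,18352,55.65,67,27,0.2
5,SCC,20760,5824,71.95,90,47,0.2
6,SCC,41056,23416,42.97,63,14,0.2
7,SCC,39776,15840,60.18,42,-1,0.2
8,SCC,133864,29816,77.73,47,5,0.2
9,SCC,123016,131160,-6.62,83,27,0.1
10,ADC,45160,8544,81.08,69,27,0.2
11,ADC,63136,20632,67.32,46,0,0.2
12,ADC,99872,51752,48.18,60,18,0.2
13,ADC,111744,29264,73.81,104,21,0.2
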