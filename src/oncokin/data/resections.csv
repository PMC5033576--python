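case_id,interval_ct2_to_surgery_days,a_cm,b_cm,c_cm,volume_printed_ml,eqdiam_printed_cm
1,20,6,4.5,3,42.41,4.33
2,21,6,5.5,4,69.12,5.09
3,18,2.5,1.6,1.6,3.35,1.86
4,36,3,2,1.5,4.71,2.08
5,5,2.5,1.8,1.5,3.53,1.89
6,39,4,3.7,3,23.25,3.54
7,7,3.5,3.3,2.5,15.12,3.07
8,3,3.5,3.5,3.3,21.17,3.43
9,28,8,7.5,5.5,172.79,6.91
10,20,2.1,1.9,1.3,2.72,1.73
11,6,4,3.5,2,14.66,3.04
13,22,4.7,4,3.1,30.52,3.88
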