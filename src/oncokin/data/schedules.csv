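case_id,day,drug
1,1,gemcitabine
1,8,gemcitabine
1,22,gemcitabine
1,29,gemcitabine
1,1,cisplatin
1,22,cisplatin
2,1,gemcitabine
2,8,gemcitabine
2,22,gemcitabine
2,29,gemcitabine
2,1,cisplatin
2,22,cisplatin
3,1,gemcitabine
3,8,gemcitabine
3,22,gemcitabine
3,30,gemcitabine
3,1,cisplatin
3,22,cisplatin
4,1,docetaxel
4,22,docetaxel
4,1,cisplatin
4,22,cisplatin
5,1,vinorelbine
5,8,vinorelbine
5,22,vinorelbine
5,29,vinorelbine
5,1,cisplatin
5,22,cisplatin
6,1,vinorelbine
6,8,vinorelbine
6,22,vinorelbine
6,29,vinorelbine
6,43,vinorelbine
6,1,cisplatin
6,22,cisplatin
6,43,cisplatin
7,1,vinorelbine
7,22,vinorelbine
7,29,vinorelbine
7,1,cisplatin
7,22,cisplatin
8,1,vinorelbine
8,8,vinorelbine
8,22,vinorelbine
8,29,vinorelbine
8,1,cisplatin
8,22,cisplatin
9,1,vinorelbine
9,8,vinorelbine
9,29,vinorelbine
9,36,vinorelbine
9,1,cisplatin
9,29,cisplatin
10,1,vinorelbine
10,8,vinorelbine
10,22,vinorelbine
10,29,vinorelbine
10,1,cisplatin
10,22,cisplatin
11,1,vinorelbine
11,8,vinorelbine
11,26,vinorelbine
11,33,vinorelbine
11,1,cisplatin
11,26,cisplatin
12,1,vinorelbine
12,8,vinorelbine
12,22,vinorelbine
12,29,vinorelbine
12,1,cisplatin
12,22,cisplatin
13,1,vinorelbine
13,8,vinorelbine
13,36,vinorelbine
13,43,vinorelbine
13,64,vinorelbine
13,71,vinorelbine
13,1,cisplatin
13,36,cisplatin
13,64,cisplatin
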