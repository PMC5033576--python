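case_id,day,drug
2,43,gemcitabine
2,50,gemcitabine
2,43,cisplatin
4,44,docetaxel
4,44,cisplatin
6,50,vinorelbine
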