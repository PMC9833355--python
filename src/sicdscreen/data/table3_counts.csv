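patient_id,group,primary,alternate,secondary
1,Normal,3,0,23
2,Normal,2613,19,0
3,Normal,17,51,0
4,Normal,1,3,1
5,Normal,0,452,14
6,Normal,2,12,277
7,Normal,1,1074,3
8,HF,8,1524,NA
9,HF,1024,815,NA
10,HF,1280,219,NA
11,HF,0,1828,NA
12,HF,2305,637,NA
13,HF,0,31,NA
14,HF,1104,5,37
15,HF,3555,4652,4054
16,HF,389,452,291
17,HF,5562,417,0
18,HF,13,400,222
19,HF,808,383,2866
20,HF,0,0,0
21,HF,2,406,1
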