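variable,full,Q1,Q2,Q3,Q4
state_n,458,60,175,134,89
ptsd,195,21,60,70,44
depression,109,7,32,34,36
anxiety,39,4,12,15,8
adhd,10,1,2,6,1
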