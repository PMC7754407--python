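variable,full,Q1,Q2,Q3,Q4
ptsd,42.58,35.00,34.29,52.24,49.44
depression,23.80,11.67,18.29,25.37,40.45
anxiety,8.52,6.67,6.86,11.19,8.99
adhd,2.18,1.67,1.14,4.48,1.12
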