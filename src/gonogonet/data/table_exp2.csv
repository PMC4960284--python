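phase,stimulus_a,stimulus_b,vector,target_or_band
training,A1,B1,100010,1
training,A1,B2,110000,0
training,B1,C1,001010,1
training,B1,C2,000110,0
training,A2,B2,010001,1
training,A2,B1,000011,0
training,B2,C2,010100,1
training,B2,C1,011000,0
test,A1,C1,101000,0.85~1.00
test,A1,C2,100100,0.00~0.15
test,A2,C2,000101,0.85~1.00
test,A2,C1,001001,0.00~0.15
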