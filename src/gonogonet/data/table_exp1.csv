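phase,stimulus_a,stimulus_b,vector,target_or_band
additional_training,X,Y,000101000,1
additional_training,Y,Z,010001000,1
additional_training,X,Z,010100000,1
training,A1,B1,100000010,1
training,A1,B2,101000000,0
training,B1,C1,000010010,1
training,B1,C2,000000110,0
training,A2,B2,001000001,1
training,A2,B1,000000011,0
training,B2,C2,001000100,1
training,B2,C1,001010000,0
test,A1,C1,100010000,0.85~1.00
test,A1,C2,100000100,0.00~0.15
test,A2,C2,000000101,0.85~1.00
test,A2,C1,000010001,0.00~0.15
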