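,N,S,V,F,Q
N,41186,1427,535,1067,0
S,317,1473,42,4,0
V,133,68,2929,89,0
F,310,14,15,49,0
Q,3,0,4,0,0
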