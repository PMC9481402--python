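symbol,atr_code,aami_class,description
N,1,N,normal beat
L,2,N,left bundle branch block beat
R,3,N,right bundle branch block beat
e,34,N,atrial escape beat
j,11,N,nodal (junctional) escape beat
A,8,S,atrial premature beat
a,4,S,aberrated atrial premature beat
J,7,S,nodal (junctional) premature beat
S,9,S,supraventricular premature beat
V,5,V,premature ventricular contraction
E,10,V,ventricular escape beat
F,6,F,fusion of ventricular and normal beat
/,12,Q,paced beat
f,38,Q,fusion of paced and normal beat
Q,13,Q,unclassifiable beat
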