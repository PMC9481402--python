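member,acc,ppv,sen,spe
1,88.71,49.03,77.66,90.68
2,88.18,47.66,83.61,89.37
3,88.60,48.81,88.36,89.78
4,86.92,44.58,85.64,87.91
5,89.80,52.36,84.96,91.23
6,83.54,38.14,84.92,83.91
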