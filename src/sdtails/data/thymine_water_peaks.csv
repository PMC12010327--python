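feature,omega_cm1,lambda_cm1,gamma_cm1
Solvent,0,715.7,54.5
Peak 1,1663,330,10
Peak 2,1243,161.6,36.55
Peak 3,1416,25.6,10
Peak 4,784,26.5,33.77
Peak 5,1376,186,10
Peak 6,1193,77.3,32.01
Peak 7,665,31.9,10
Peak 8,442,14.9,48.46
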