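label,x,y
Fp1,-0.309,0.951
Fp2,0.309,0.951
F7,-0.809,0.588
F3,-0.354,0.354
Fz,0.0,0.5
F4,0.354,0.354
F8,0.809,0.588
T3,-1.0,0.0
C3,-0.5,0.0
Cz,0.0,0.0
C4,0.5,0.0
T4,1.0,0.0
T5,-0.809,-0.588
P3,-0.354,-0.354
Pz,0.0,-0.5
P4,0.354,-0.354
T6,0.809,-0.588
O1,-0.309,-0.951
O2,0.309,-0.951
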