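# Atomic solvation parameters, kJ mol^-1 A^-2
# class  coefficient
C         0.0669
N        -0.0251
O        -0.0251
O_CHARGED -0.1004
N_CHARGED -0.2092
S         0.0879
H         0.0
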