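ZINC000001
     RDKit          3D

  3  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    1.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
$$$$
ZINC000002
     RDKit          3D

  4  0  0  0  0  0  0  0  0  0999 V2000
    2.0000    1.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.5000    1.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0000    2.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0000    1.0000    1.5000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
$$$$
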