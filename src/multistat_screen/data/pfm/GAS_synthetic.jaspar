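>GAS.synthetic GAS_synthetic
A  [  25    2    2    2    2   25    2    2   96   96   55 ]
C  [  12    1    1   96   96   55    1    1    2    2   25 ]
G  [   8    1    1    1    1   12   96   96    1    1   12 ]
T  [  55   96   96    1    1    8    1    1    1    1    8 ]
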