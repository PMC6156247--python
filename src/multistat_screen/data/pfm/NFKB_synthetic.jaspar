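>NFKB.synthetic NFKB_synthetic
A  [   2    2    2   96    2    2    2    2    2    2 ]
C  [   1    1    1    2   96    1    1    1   96   96 ]
G  [  96   96   96    1    1    1    1    1    1    1 ]
T  [   1    1    1    1    1   96   96   96    1    1 ]
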