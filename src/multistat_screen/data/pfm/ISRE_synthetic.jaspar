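>ISRE.synthetic ISRE_synthetic
A  [  96    2    2    2    2    2   40   10    2    2    2    2 ]
C  [   2    1    1    1    1   96   30   40    1    1    1   96 ]
G  [   1   96    1    1    1    1   20   30    1    1    1    1 ]
T  [   1    1   96   96   96    1   10   20   96   96   96    1 ]
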