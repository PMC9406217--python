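>synthetic_forkhead
A  [ 30 25  2  2  2  2  2 94  3 25 30 25 ]
C  [ 25 25  2  2  2  2  2  2 70 25 20 25 ]
G  [ 25 25 94  2  2  2  2  2  3 25 30 25 ]
T  [ 20 25  2 94 94 94 94  2 24 25 20 25 ]
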