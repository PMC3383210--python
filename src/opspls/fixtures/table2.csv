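id,observed,predicted
A0,7.951,7.622
B5,7.369,6.954
C2,6.533,6.207
C4,6.696,7.069
C9,7.542,7.601
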