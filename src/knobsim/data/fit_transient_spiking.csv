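seq,element_id,raw_value
1,11,42
2,4,60
3,4,51
4,7,90
5,7,107
6,1,94
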