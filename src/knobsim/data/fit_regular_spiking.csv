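seq,element_id,raw_value
1,11,20
2,11,60
3,11,42
4,10,86
5,3,64
6,6,54
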