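seq,element_id,raw_value
1,9,0
2,3,40
3,3,32
4,6,33
5,1,64
6,16,127
7,4,70
8,10,65
9,5,71
10,8,37
11,2,69
12,11,13
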