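tree_id,detect,actual,predicted,e1,e2,rate_printed
1,44,63,62,19,1,1.5
2,46,72,64,26,8,11.1
3,37,59,56,22,3,5.0
4,38,55,56,17,1,1.8
5,77,106,108,29,2,1.8
6,67,90,91,23,1,1.1
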