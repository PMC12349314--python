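tree_id,detect,actual,predicted,e1,e2,rate_printed
1,47,65,70,18,5,7.6
2,43,73,63,30,10,13.6
3,37,58,55,21,3,5.1
4,42,56,61,14,5,8
5,68,107,100,39,7,6.5
6,64,93,94,29,1,1.0
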