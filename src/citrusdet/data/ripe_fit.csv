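tree_id,detect,actual
1,43,58
2,49,63
3,62,82
4,58,88
5,73,101
6,88,121
7,88,135
8,72,97
9,34,56
10,41,59
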