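tree_id,detect,actual
1,45,55
2,41,61
3,54,80
4,49,79
5,65,98
6,79,119
7,86,131
8,76,94
9,38,59
10,39,56
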