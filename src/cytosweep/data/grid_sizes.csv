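xdim,ydim
2,2
2,3
2,4
3,3
3,4
4,4
4,5
5,5
5,6
6,6
7,7
8,8
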