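patient,target,residual_margin_pct
1,1,5.4
2,1,2.8
3,1,3.1
3,2,9.2
3,3,12.1
3,4,1.9
4,1,0
4,2,4.9
5,1,8.1
6,1,14.1
6,2,10.1
7,1,4.1
8,1,3.3
8,2,3.1
8,3,0
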