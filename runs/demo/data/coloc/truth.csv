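sample,shared_fraction,n_fibers,n_shared
0,0.8007889546351085,507,406
1,0.8003952569169961,506,405
2,0.8003952569169961,506,405
3,0.7996031746031746,504,403
4,0.8,505,404
5,0.8003952569169961,506,405
6,0.8003952569169961,506,405
7,0.7992125984251969,508,406
8,0.8,505,404
9,0.8003952569169961,506,405
10,0.8003952569169961,506,405
11,0.8,505,404
12,0.8,505,404
13,0.8,505,404
14,0.8007889546351085,507,406
15,0.8,505,404
16,0.8003952569169961,506,405
17,0.8003952569169961,506,405
18,0.8003952569169961,506,405
19,0.8003952569169961,506,405
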