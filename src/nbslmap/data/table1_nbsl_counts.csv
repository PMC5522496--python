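h_deg,v_deg,count,bracketed
15,3,1,1
13,2,7,0
14,2,3,1
15,2,6,0
16,2,2,1
17,2,2,1
11,1,1,1
12,1,7,0
13,1,47,0
14,1,61,0
15,1,78,0
16,1,34,0
17,1,13,0
18,1,2,1
19,1,1,1
11,0,13,0
12,0,74,0
13,0,183,0
14,0,259,0
15,0,243,0
16,0,124,0
17,0,58,0
18,0,8,0
19,0,3,1
21,0,1,1
10,-1,1,1
11,-1,21,0
12,-1,196,0
13,-1,625,0
14,-1,1021,0
16,-1,447,0
17,-1,178,0
18,-1,31,0
19,-1,4,1
20,-1,1,1
7,-2,1,1
10,-2,2,1
11,-2,45,0
12,-2,241,0
13,-2,703,0
14,-2,909,0
15,-2,797,0
16,-2,376,0
17,-2,186,0
18,-2,24,0
19,-2,5,0
11,-3,5,0
12,-3,103,0
13,-3,667,0
14,-3,938,0
15,-3,843,0
16,-3,415,0
17,-3,154,0
18,-3,25,0
19,-3,3,1
10,-4,1,1
11,-4,5,0
12,-4,25,0
13,-4,150,0
14,-4,321,0
15,-4,274,0
16,-4,125,0
17,-4,60,0
18,-4,3,1
19,-4,2,1
11,-5,1,1
12,-5,2,1
13,-5,31,0
14,-5,75,0
15,-5,82,0
16,-5,51,0
17,-5,15,0
18,-5,2,1
19,-5,1,1
14,-6,4,1
15,-6,10,0
16,-6,8,0
17,-6,3,1
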