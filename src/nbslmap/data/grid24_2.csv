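h_deg,v_deg,analysis
-9,21,1
-3,21,1
3,21,1
9,21,1
-15,15,1
-9,15,1
-3,15,1
3,15,1
9,15,1
15,15,1
-21,9,1
-15,9,1
-9,9,1
-3,9,1
3,9,1
9,9,1
15,9,1
21,9,1
-27,3,1
-21,3,1
-15,3,1
-9,3,1
-3,3,1
3,3,1
9,3,1
15,3,0
21,3,1
-27,-3,1
-21,-3,1
-15,-3,1
-9,-3,1
-3,-3,1
3,-3,1
9,-3,1
15,-3,0
21,-3,1
-21,-9,1
-15,-9,1
-9,-9,1
-3,-9,1
3,-9,1
9,-9,1
15,-9,1
21,-9,1
-15,-15,1
-9,-15,1
-3,-15,1
3,-15,1
9,-15,1
15,-15,1
-9,-21,1
-3,-21,1
3,-21,1
9,-21,1
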