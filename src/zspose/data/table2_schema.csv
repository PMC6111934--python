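joint,kind,categories,sensor_ids
He,classification,up;down;left;right;front,head
S(L),classification,up;down;left;right;front,shoulder_l;upperarm_l
S(R),classification,up;down;left;right;front,shoulder_r;upperarm_r
E(L),regression,,upperarm_l;lowerarm_l
E(R),regression,,upperarm_r;lowerarm_r
Wr(L),regression,,lowerarm_l;hand_l
Wr(R),regression,,lowerarm_r;hand_r
Ha(L),classification,normal;grasp;pointing,hand_l;finger_l1;finger_l2;finger_l3;finger_l4;finger_l5;finger_l6;finger_l7
Ha(R),classification,normal;grasp;pointing,hand_r;finger_r1;finger_r2;finger_r3;finger_r4;finger_r5;finger_r6;finger_r7
Wa,classification,straight;bend;twist-L;twist-R,spine;hip
HJ(L),regression,,hip;upperleg_l
HJ(R),regression,,hip;upperleg_r
K(L),regression,,upperleg_l;lowerleg_l
K(R),regression,,upperleg_r;lowerleg_r
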