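pose,He,S(L),S(R),E(L),E(R),Wr(L),Wr(R),Ha(L),Ha(R),Wa,HJ(L),HJ(R),K(L),K(R)
Standing,front,down,down,0,0,0.5,0.5,normal,normal,straight,0,0,0,0
Sitting,front,down,down,0,0,0.5,0.5,normal,normal,straight,0.5,0.5,0.5,0.5
Squatting,front,down,down,0,0,0.5,0.5,normal,normal,straight,1,1,1,1
Raising arm (L),front,up,down,0,0,0.5,0.5,normal,normal,straight,0,0,0,0
Raising arm (R),front,down,up,0,0,0.5,0.5,normal,normal,straight,0,0,0,0
Pointing (L),front,front,down,0,0,0.5,0.5,pointing,normal,straight,0,0,0,0
Pointing (R),front,down,front,0,0,0.5,0.5,normal,pointing,straight,0,0,0,0
Folding arm,front,down,down,0.5,0.5,0.5,0.5,normal,normal,straight,0,0,0,0
Deep breathing,front,left,right,0,0,0.5,0.5,normal,normal,straight,0,0,0,0
Stretching up,front,up,up,0,0,0,0,normal,normal,straight,0,0,0,0
Stretching forward,front,front,front,0,0,0,0,normal,normal,straight,0,0,0,0
Waist bending,front,down,down,0,0,0.5,0.5,normal,normal,bend,0,0,0,0
Waist twisting (L),left,left,left,0,0.5,0.5,0.5,normal,normal,twist-L,0,0,0,0
Waist twisting (R),right,right,right,0.5,0,0.5,0.5,normal,normal,twist-R,0,0,0,0
Heel to back (L),front,down,down,0,0,0.5,0.5,grasp,normal,straight,0,0,1,0
Heel to back (R),front,down,down,0,0,0.5,0.5,normal,grasp,straight,0,0,0,1
Stretching calf (L),front,front,front,0,0,0,0,normal,normal,straight,0,0.3,0,0.3
Stretching calf (R),front,front,front,0,0,0,0,normal,normal,straight,0.3,0,0.3,0
Boxing,front,down,down,1,1,0.5,0.5,grasp,grasp,straight,0,0,0,0
Baseball hitting,left,down,down,0.5,0.5,0.5,0.5,grasp,grasp,straight,0.5,0,0.5,0
Skiing,front,down,down,0.5,0.5,0.5,0.5,grasp,grasp,straight,0.3,0.3,0.3,0.3
Thinking,front,down,down,0.5,1,0.5,0,normal,normal,straight,1,1,0.5,0.5
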