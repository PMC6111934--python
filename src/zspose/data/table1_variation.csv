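pose,joint,alternatives
Sitting,E(L),0;1
Sitting,E(R),0;1
Sitting,Ha(L),normal;grasp
Sitting,Ha(R),normal;grasp
Squatting,E(L),0;1
Squatting,E(R),0;1
Squatting,Ha(L),normal;grasp
Squatting,Ha(R),normal;grasp
Raising arm (L),E(R),0;1
Raising arm (L),Ha(R),normal;grasp
Raising arm (R),E(L),0;1
Raising arm (R),Ha(L),normal;grasp
Pointing (L),E(R),0;1
Pointing (L),Ha(R),normal;grasp
Pointing (R),E(L),0;1
Pointing (R),Ha(L),normal;grasp
Folding arm,Wr(L),0.5;1
Folding arm,Wr(R),0.5;1
Folding arm,Ha(L),normal;grasp
Folding arm,Ha(R),normal;grasp
Deep breathing,He,front;up
Stretching up,He,front;up
Stretching forward,Wa,straight;bend
Waist twisting (L),He,left;front
Waist twisting (L),S(L),left;down
Waist twisting (L),S(R),left;down
Waist twisting (L),E(R),0.5;0
Waist twisting (R),He,right;front
Waist twisting (R),S(L),right;down
Waist twisting (R),S(R),right;down
Waist twisting (R),E(L),0.5;0
Heel to back (L),S(R),down;front
Heel to back (L),E(R),0;0.5
Heel to back (L),Ha(R),normal;grasp
Heel to back (R),S(L),down;front
Heel to back (R),E(L),0;0.5
Heel to back (R),Ha(L),normal;grasp
Stretching calf (L),He,front;down
Stretching calf (R),He,front;down
Boxing,He,front;down
Baseball hitting,He,left;front
Skiing,He,front;down
Thinking,He,front;down
Thinking,Wr(L),0.5;0
Thinking,Ha(L),normal;grasp
Thinking,Ha(R),normal;grasp
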