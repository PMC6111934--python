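pose,He,S(L),S(R),E(L),E(R),Wr(L),Wr(R),Ha(L),Ha(R),Wa,HJ(L),HJ(R),K(L),K(R)
Standing,1,1,1,1,1,1,1,1,1,1,1,1,1,1
Sitting,1,1,1,0,0,0,0,0,0,1,1,1,1,1
Squatting,1,1,1,0,0,0,0,0,0,1,1,1,1,1
Raising arm (L),1,1,1,1,0,1,0,1,0,1,1,1,1,1
Raising arm (R),1,1,1,0,1,0,1,0,1,1,1,1,1,1
Pointing (L),1,1,1,1,0,1,0,1,0,1,1,1,1,1
Pointing (R),1,1,1,0,1,0,1,0,1,1,1,1,1,1
Folding arm,1,1,1,1,1,0,0,0,0,1,1,1,1,1
Deep breathing,0,1,1,1,1,1,1,1,1,1,1,1,1,1
Stretching up,0,1,1,1,1,1,1,1,1,1,1,1,1,1
Stretching forward,1,1,1,1,1,1,1,1,1,0,1,1,1,1
Waist bending,0,0,0,0,0,0,0,0,0,1,1,1,1,1
Waist twisting (L),1,0,0,0,0,0,0,0,0,1,1,1,1,1
Waist twisting (R),1,0,0,0,0,0,0,0,0,1,1,1,1,1
Heel to back (L),1,1,0,1,0,0,0,0,0,1,1,1,1,1
Heel to back (R),1,0,1,0,1,0,0,0,0,1,1,1,1,1
Stretching calf (L),0,1,1,1,1,1,1,1,1,1,1,1,1,1
Stretching calf (R),0,1,1,1,1,1,1,1,1,1,1,1,1,1
Boxing,0,1,1,1,1,1,1,1,1,1,1,1,1,1
Baseball hitting,0,0,0,1,1,0,0,1,1,1,1,1,1,1
Skiing,0,1,1,1,1,1,1,1,1,0,1,1,1,1
Thinking,0,1,1,0,1,0,0,0,0,0,1,1,1,1
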