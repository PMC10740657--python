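species,eru_ids,zones,zones_2090,buffer_m
flammulated_owl,MCA;MCFF;PPF;PPE,all,,1000
western_screech_owl,PJW;MPO;MEW;PJS;PJES;PJDS;PJG;JUG,all,,1000
whiskered_screech_owl,PPF;PPE;MPO;MEW,Z1,Z1;Z2;Z3,1000
great_horned_owl,SFF;BPF;MCA;MCFF;PPF;PPE;PJW;MPO;MEW;PJS;PJES;PJDS;PJG;JUG,all,,1000
northern_pygmy_owl,SFF;BPF;MCA;MCFF;PPF;PPE;PJW;MPO;MEW,all,,1000
long_eared_owl,SFF;BPF;MCA;MCFF;PPF;PPE;PJW;MPO;MEW,all,,1000
boreal_owl,SFF;BPF,Z4,,1000
northern_saw_whet_owl,SFF;BPF;MCA;MCFF;PPF;PPE,Z2;Z3;Z4,,1000
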