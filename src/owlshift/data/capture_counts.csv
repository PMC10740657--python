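species,within_model,within_buffer,outside_buffer,total,sims_outperform_no_buffer,sims_outperform_with_buffer
flammulated_owl,248,30,13,291,0,0
western_screech_owl,34,39,60,137,34,0
whiskered_screech_owl,71,41,0,112,307,0
great_horned_owl,125,13,10,148,500,500
northern_pygmy_owl,47,21,1,69,0,0
long_eared_owl,14,4,5,23,17,0
boreal_owl,17,3,0,20,0,0
northern_saw_whet_owl,22,6,6,34,0,0
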