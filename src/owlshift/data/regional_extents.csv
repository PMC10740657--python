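species,current_ha,projected_ha,published_pct_change
flammulated_owl,4684000,714000,-85
western_screech_owl,3186000,1511000,-55
whiskered_screech_owl,714000,677000,-5
great_horned_owl,16984000,11273000,-35
northern_pygmy_owl,8267000,2021000,-75
long_eared_owl,8263000,2623000,-70
boreal_owl,306000,42000,-85
northern_saw_whet_owl,5080000,2008000,-60
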