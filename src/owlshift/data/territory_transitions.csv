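current,projected,count
Dry Forest,Dry Forest,1
Dry Forest,Madrean Woodland,9
Dry Forest,Pinyon-Juniper,122
Mixed Conifer with Aspen,Dry Forest,4
Pinyon-Juniper,Pinyon-Juniper,2
Pinyon-Juniper,Gambel Oak Shrubland,1
Riparian,Riparian,7
Upland Shrub,Gambel Oak Shrubland,2
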