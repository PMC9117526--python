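species,boneless_per_live,boneless_per_carcass
sheep,0.33,0.67
chicken,0.65,0.75
beef,0.46,0.83
pork,0.43,0.62
fish,0.54,
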