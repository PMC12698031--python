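trait,kind,category
size_class,ordinal,<200
size_class,ordinal,200-600
size_class,ordinal,>600
feeding_type,categorical,microphagous
feeding_type,categorical,raptorial_rotifer
feeding_type,categorical,stationary_suspension
feeding_type,categorical,tactile_raptorial
feeding_type,categorical,D_filtration
feeding_type,categorical,B_filtration
feeding_type,categorical,C_filtration
feeding_type,categorical,S_filtration
trophic_group,categorical,herbivorous
trophic_group,categorical,omnivorous
trophic_group,categorical,carnivorous
trophic_group,categorical,detritivorous
habitat,categorical,littoral
habitat,categorical,pelagic
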