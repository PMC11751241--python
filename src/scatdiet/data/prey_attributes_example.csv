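prey_species,origin,mean_mass_kg,provenance
blue_sheep,wild,55,example
dog,domestic,20,example
domestic_goat,domestic,35,example
domestic_sheep,domestic,35,example
himalayan_marmot,wild,6,example
horse,domestic,250,example
least_weasel,wild,0.1,example
mountain_weasel,wild,0.25,example
pika,wild,0.15,example
stone_marten,wild,1.5,example
yak,domestic,250,example
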