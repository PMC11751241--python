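prey_species,common_label,origin,snow_leopard_fo,snow_leopard_rb,wolf_fo,wolf_rb
blue_sheep,Blue Sheep,wild,24.83,20.88,9.43,6.99
dog,Dog,domestic,3.57,2.38,8.48,4.96
domestic_goat,Domestic Goat,domestic,19.90,15.87,29.15,20.48
domestic_sheep,Domestic Sheep,domestic,1.53,1.15,1.85,1.23
himalayan_marmot,Himalayan Marmot,wild,12.76,6.95,7.26,3.45
horse,Horse,domestic,3.40,7.24,6.48,12.30
least_weasel,Least Weasel,wild,5.10,2.60,4.63,2.06
mountain_weasel,Mountain Weasel,wild,3.57,1.88,,
pika,Pika,wild,5.61,2.78,4.33,1.87
stone_marten,Stone Marten,wild,3.41,1.80,6.46,2.97
yak,Yak,domestic,16.33,36.47,21.93,43.68
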