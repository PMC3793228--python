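hotspot,area_km2,species_total,species_endemic,species_per_km2_printed,mean_rate_printed,speciation_density_printed
California Floristic Province,293804,8000,2124,0.027,0.39,1.32e-6
Cape Floristic Region,78555,9000,6210,0.196,0.40,5.05e-6
Cerrado,2031990,12669,4215,0.060,0.58,0.29e-6
Hawaiian Archipelago,28311,1004,900,0.035,0.73,25.68e-6
Mediterranean Floristic Province,2085292,22500,11700,0.010,1.07,0.52e-6
Paramos,35000,3431,,0.098,1.36,38.80e-6
Southwest Australia,356717,5500,2948,0.015,0.14,0.38e-6
Succulent Karoo,102691,6350,2439,0.062,0.76,7.38e-6
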