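lineage_id,family,hotspot,n_species,crown_age_min,crown_age_mean,crown_age_max,pleistocene_count
Aragoa,Plantaginaceae,Paramos,17,0.12,0.42,0.92,5
Arcytophyllum,Rubiaceae,Paramos,14,6.48,10.96,16.36,1
Berberis,Berberidaceae,Paramos,32,0.07,3.80,9.7,4
Calceolaria,Calceolariaceae,Paramos,65,1.42,2.50,3.51,23
Draba,Brassicaceae,Paramos,55,1.60,3.05,4.1,23
Espeletiinae,Asteraceae,Paramos,120,2.42,4.04,5.92,21
Festuca,Poaceae,Paramos,36,1.87,4.28,7.66,3
Jamesonia+Eriosorus,Pteridaceae,Paramos,32,,7.60,,0
Lupinus,Fabaceae,Paramos,66,1.18,1.47,1.76,32
Lysipomia,Campanulaceae,Paramos,27,6.61,8.96,11.19,13
Oreobolus,Cyperaceae,Paramos,5,1.67,3.01,4.71,3
Puya,Bromeliaceae,Paramos,46,0.26,0.80,1.58,10
Valeriana,Valerianaceae,Paramos,53,9.46,14.58,19.69,
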