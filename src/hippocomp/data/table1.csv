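species_label,group_id,latin_name,n_female,n_male,n_unknown,mean_age_months,age_sd_months,order_name,family
"House mouse, wild-type",house_mouse,Mus musculus domesticus,0,5,0,3.5,,Rodentia,Muridae
"House mouse, DBA",dba,Mus musculus domesticus,6,0,0,3.0,,Rodentia,Muridae
"House mouse, C57BL/6",c57bl6,Mus musculus domesticus,11,2,0,3.0,,Rodentia,Muridae
"Rat, Sprague-Dawley",brown_rat,Rattus norvegicus,0,5,0,5.0,,Rodentia,Muridae
"Rat, Wistar",brown_rat,Rattus norvegicus,5,5,0,1.5,0.5,Rodentia,Muridae
Yellow-necked wood mouse,yellow_necked_wood_mouse,Apodemus flavicollis,2,4,0,4.3,0.5,Rodentia,Muridae
Harvest mouse,harvest_mouse,Micromys minutus,0,0,5,,,Rodentia,Muridae
Sand rat,sand_rat,Psammomys obesus,0,6,0,2.7,0.3,Rodentia,Cricetidae
Bank vole,bank_vole,Myodes glareolus,1,3,0,7.4,6.9,Rodentia,Cricetidae
Muskrat,muskrat,Ondatra zibethicus,3,3,0,9.5,4.2,Rodentia,Cricetidae
Hamster,hamster,Mesocricetus auratus,0,6,0,2.6,0.2,Rodentia,Cricetidae
Cotton rat,cotton_rat,Sigmodon hispidus,0,6,0,2.0,0.1,Rodentia,Cricetidae
Highveld mole-rat,highveld_mole_rat,Cryptomys hottentotus,6,0,0,20.3,9.2,Rodentia,Bathyergidae
Cape mole-rat,cape_mole_rat,Georychus capensis,4,2,0,26.0,10.7,Rodentia,Bathyergidae
Naked mole-rat,naked_mole_rat,Heterocephalus glaber,1,4,0,39.3,2.8,Rodentia,Bathyergidae
Eastern rock sengi,sengi,Elephantulus myurus,4,4,0,8.8,1.8,Macroscelidea,Macroscelididae
Dog,dog,Canis lupus familiaris,0,0,10,109.1,63.3,Carnivora,Canidae
"Pig, domestic",pig,Sus scrofa domestica,5,0,0,3.2,,Artiodactyla,Suidae
Common marmoset,marmoset,Callithrix jacchus,2,3,0,53.6,41.6,Primates,Callitrichidae
Rhesus monkey,rhesus_monkey,Macaca mulatta,0,8,0,14.0,21.4,Primates,Cercopithecidae
Human,human,Homo sapiens,17,56,0,777.0,260.8,Primates,Hominidae
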