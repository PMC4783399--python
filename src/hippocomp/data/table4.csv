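group_id,r_gc_hil,r_gc_ca3,r_ca3_ca1,r_ca1_sub
dog,0.041,0.165,3.044,0.694
pig,0.166,0.144,2.686,0.513
human,0.087,0.152,4.194,0.379
rhesus_monkey,0.048,0.061,2.599,0.421
marmoset,0.074,0.158,1.667,0.323
cape_mole_rat,0.143,1.122,0.717,0.756
highveld_mole_rat,0.09,0.639,0.898,0.766
naked_mole_rat,0.05,0.635,0.64,0.803
muskrat,0.072,0.302,1.526,0.452
bank_vole,0.026,0.194,1.089,0.527
c57bl6,0.029,0.263,1.31,0.719
dba,0.028,0.361,1.113,0.722
house_mouse,0.039,0.443,1.081,0.629
brown_rat,0.047,0.231,1.013,0.993
harvest_mouse,0.022,0.228,0.942,0.697
yellow_necked_wood_mouse,0.054,0.313,1.608,0.396
sand_rat,0.061,0.46,1.221,0.481
hamster,0.05,0.331,1.274,0.606
cotton_rat,0.045,0.301,1.49,0.423
sengi,0.051,0.055,3.443,0.171
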