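group_id,marker,mean_count,sd_count,mean_ce,ce2_cv2,sections_mean,sections_sd,cells_counted_mean,cells_counted_sd,counting
dba,Ki67,1753,184,0.07,0.42,14.0,0.8,351.0,37.0,exhaustive
c57bl6,Ki67,4505,765,0.06,0.11,14.0,2.1,901.0,153.0,exhaustive
house_mouse,Ki67,1630,268,0.07,0.19,13.0,1.2,326.0,53.0,exhaustive
hamster,Ki67,2813,1240,0.07,0.03,7.0,0.5,281.0,124.0,exhaustive
sand_rat,Ki67,2452,591,0.1,0.17,8.0,1.3,245.0,59.0,exhaustive
cotton_rat,Ki67,5053,2378,0.09,0.04,8.0,1.2,505.0,18.0,exhaustive
muskrat,Ki67,2487,657,0.09,0.11,10.0,1.2,178.0,47.0,exhaustive
yellow_necked_wood_mouse,Ki67,15030,3556,0.06,0.06,12.0,3.0,2505.0,593.0,exhaustive
bank_vole,Ki67,5373,2830,0.08,0.02,14.0,1.0,896.0,472.0,exhaustive
dba,DCX,7372,940,0.11,0.83,15.0,1.1,200.0,42.0,fractionator
c57bl6,DCX,21080,3072,0.07,0.25,14.0,1.0,315.0,96.0,fractionator
house_mouse,DCX,10677,2609,0.09,0.14,13.0,1.6,123.0,30.0,fractionator
hamster,DCX,7450,1069,0.07,0.26,8.0,0.8,267.0,51.0,fractionator
sand_rat,DCX,10850,3587,0.12,0.15,9.0,1.0,1085.0,359.0,fractionator
cotton_rat,DCX,9103,1484,0.05,0.1,9.0,0.8,902.0,155.0,fractionator
muskrat,DCX,11655,3781,0.08,0.06,9.0,1.2,817.0,255.0,fractionator
yellow_necked_wood_mouse,DCX,57682,4382,0.1,1.59,7.0,0.8,210.0,47.0,fractionator
bank_vole,DCX,38833,24082,0.08,0.02,7.0,0.0,376.0,93.0,fractionator
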