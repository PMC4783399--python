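group_id,population,mean_count,sd_count,mean_ce,ce2_cv2,frame_um,grid_um,sections_mean,sections_sd,cells_counted_mean,cells_counted_sd,note
dba,GC,409981,22614,0.13,5.45,7.0,100.0,12.0,0.8,145.0,60.0,
c57bl6,GC,438187,137143,0.13,1.06,7.0,100.0,11.0,1.6,144.0,16.0,
house_mouse,GC,476984,72686,0.09,0.34,10.0,100.0,20.0,1.1,204.0,99.0,
highveld_mole_rat,GC,588647,93514,0.08,0.32,12.0,140.0,15.0,0.2,216.0,30.0,
cape_mole_rat,GC,488676,77599,0.11,0.45,18.0,324.0,16.0,0.0,164.0,62.0,
naked_mole_rat,GC,380255,34806,0.07,0.7,10.0,120.0,21.0,0.4,353.0,23.0,
sand_rat,GC,611424,112574,0.1,0.3,12.0,160.0,16.0,1.2,210.0,40.0,
hamster,GC,497717,88880,0.09,0.27,12.0,120.0,15.0,0.8,221.0,27.0,
cotton_rat,GC,613446,75937,0.08,0.42,12.0,120.0,16.0,0.6,240.0,34.0,
muskrat,GC,1415956,82545,0.1,2.76,45.0,180.0,16.0,2.8,213.0,52.0,
yellow_necked_wood_mouse,GC,1437135,213879,0.07,0.24,10.0,210.0,31.0,1.8,263.0,33.0,
bank_vole,GC,2042739,211439,0.07,0.4,10.0,210.0,25.0,4.7,380.0,88.0,
marmoset,GC,2498487,431224,0.07,0.18,15.0,120.0,13.0,1.5,697.0,78.0,
dba,HIL,10487,1212,0.13,1.37,30.0,70.0,12.0,1.2,148.0,48.0,
c57bl6,HIL,13029,2267,0.13,0.49,30.0,70.0,11.0,1.6,126.0,19.0,
house_mouse,HIL,18561,3099,0.11,0.47,30.0,70.0,9.0,0.9,215.0,36.0,
highveld_mole_rat,HIL,53219,5697,0.13,1.26,40.0,120.0,9.0,0.4,199.0,19.0,
cape_mole_rat,HIL,71216,12930,0.13,0.6,30.0,150.0,10.6,1.2,91.0,21.0,
naked_mole_rat,HIL,19365,2765,0.15,1.17,40.0,70.0,9.0,0.4,386.0,61.0,
sand_rat,HIL,37742,5494,0.08,0.33,45.0,140.0,16.0,1.0,223.0,22.0,
hamster,HIL,26769,5894,0.1,0.2,45.0,120.0,15.0,1.7,163.0,32.0,
cotton_rat,HIL,27658,3033,0.08,0.58,45.0,120.0,15.0,0.8,163.0,11.0,
muskrat,HIL,104394,15103,0.16,1.32,45.0,210.0,16.0,2.3,171.0,36.0,
yellow_necked_wood_mouse,HIL,78578,7406,0.09,0.82,40.0,170.0,14.0,1.7,220.0,38.0,
bank_vole,HIL,53695,6856,0.13,1.01,40.0,140.0,8.0,1.0,168.0,15.0,
marmoset,HIL,187457,12391,0.104,2.52,40.0,200.0,13.0,1.3,159.0,19.0,
dba,CA3,155129,16621,0.12,1.23,11.0,100.0,15.0,1.2,146.0,47.0,
c57bl6,CA3,113603,29322,0.11,3.71,11.0,100.0,13.0,1.7,97.0,10.0,
house_mouse,CA3,213077,36953,0.12,0.51,11.0,100.0,10.0,0.8,165.0,20.0,
highveld_mole_rat,CA3,374376,28207,0.1,1.61,18.0,160.0,11.0,0.4,153.0,8.0,
cape_mole_rat,CA3,550413,71336,0.1,0.66,15.0,200.0,12.5,1.2,101.0,17.0,
naked_mole_rat,CA3,249021,44854,0.08,0.18,15.0,130.0,12.0,0.4,205.0,17.0,
sand_rat,CA3,285537,56815,0.1,0.27,25.0,250.0,18.0,1.5,184.0,39.0,
hamster,CA3,171799,27378,0.1,0.36,25.0,160.0,18.0,1.0,179.0,25.0,
cotton_rat,CA3,184583,21957,0.08,0.47,25.0,160.0,18.0,0.8,187.0,15.0,
muskrat,CA3,432250,61979,0.11,0.61,25.0,260.0,20.0,2.9,138.0,38.0,
yellow_necked_wood_mouse,CA3,454510,47889,0.09,0.65,15.0,190.0,14.0,1.5,142.0,14.0,
bank_vole,CA3,409606,77249,0.09,0.26,15.0,140.0,9.0,0.5,185.0,20.0,
marmoset,CA3,392291,35139,0.09,0.95,30.0,200.0,13.0,1.1,185.0,29.0,
dba,CA1,162744,21729,0.13,1.09,11.0,100.0,16.0,2.8,153.0,66.0,
c57bl6,CA1,155745,51368,0.14,1.51,11.0,100.0,13.0,1.7,130.0,8.0,
house_mouse,CA1,233670,56389,0.1,0.17,11.0,100.0,12.0,0.6,174.0,23.0,
highveld_mole_rat,CA1,338455,29375,0.12,2.12,18.0,160.0,12.0,0.8,141.0,12.0,
cape_mole_rat,CA1,415012,132131,0.12,0.15,15.0,180.0,14.0,1.4,97.0,25.0,
naked_mole_rat,CA1,158693,18884,0.1,0.76,15.0,110.0,13.0,0.7,183.0,11.0,
sand_rat,CA1,359291,70170,0.11,0.32,25.0,250.0,19.0,1.2,236.0,7.0,
hamster,CA1,221382,34246,0.1,0.44,25.0,160.0,18.0,1.0,230.0,29.0,
cotton_rat,CA1,275219,11044,0.08,3.51,25.0,160.0,18.0,0.8,280.0,18.0,
muskrat,CA1,663434,81379,0.1,0.65,25.0,260.0,20.0,2.9,216.0,63.0,
yellow_necked_wood_mouse,CA1,740667,91568,0.1,0.6,10.0,160.0,16.0,1.6,154.0,14.0,
bank_vole,CA1,455249,93897,0.1,0.24,15.0,130.0,10.0,0.5,230.0,37.0,
marmoset,CA1,656509,41394,0.12,4.54,30.0,320.0,14.0,1.0,173.0,54.0,
dba,SUB,119944,12015,0.11,1.16,25.0,140.0,15.0,1.4,156.0,59.0,
c57bl6,SUB,108479,22932,0.1,0.57,18.0,140.0,12.0,1.7,128.0,13.0,
house_mouse,SUB,147146,32839,0.1,0.21,18.0,140.0,12.0,0.9,145.0,24.0,
highveld_mole_rat,SUB,263138,33554,0.09,0.5,20.0,150.0,12.0,0.5,154.0,20.0,
cape_mole_rat,SUB,313749,62378,0.1,0.26,20.0,190.0,13.0,1.6,112.0,22.0,reconstructed
naked_mole_rat,SUB,131505,33019,0.11,0.13,20.0,130.0,12.0,1.1,192.0,35.0,
sand_rat,SUB,173602,28260,0.08,0.25,45.0,320.0,18.0,1.2,259.0,100.0,
hamster,SUB,134379,18230,0.07,0.28,45.0,200.0,18.0,0.8,286.0,32.0,
cotton_rat,SUB,117120,9493,0.08,0.95,45.0,190.0,18.0,0.8,282.0,20.0,
muskrat,SUB,302230,31484,0.09,0.72,45.0,350.0,18.0,3.4,179.0,23.0,
yellow_necked_wood_mouse,SUB,295464,38801,0.09,0.42,20.0,180.0,15.0,1.5,176.0,23.0,
bank_vole,SUB,241765,42119,0.1,0.3,20.0,140.0,11.0,0.6,183.0,20.0,
marmoset,SUB,216992,31991,0.12,0.67,18.0,240.0,14.0,1.7,132.0,60.0,
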