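node,subunit,ba,aal,tal_x,tal_y,tal_z,condition
1,115,,Pons_R,7,-23,-26,positive
2,133,R.BA53.1,Amygdala_R,25,-2,-16,positive
3,149,L.BA49.1,Putamen_L,-23,4,2,positive
4,154,L.BA4.1,Pretcentral_L,-57,-9,28,positive
5,159,,Culmen_L,-44,-53,-36,positive
6,165,L.BA18.8,Cuneus_L,-4,-90,15,positive
7,169,L.BA45.2,Insula_L,-32,22,4,positive
8,174,,Cerebellum_8_L,-20,-65,-40,positive
9,177,L.BA6.4,Inferior Frontal Gyrus,-41,9,31,positive
10,190,L.BA7.6,Occipital_Sup_L,-14,-68,29,positive
11,195,L.BA40.1,Inferior Parietal Lobule,-57,-28,33,positive
12,201,L.BA37.1,Temporal_Mid_L,-57,-48,-9,positive
13,203,L.BA6.6,Middle Frontal Gyrus,-24,11,51,positive
14,211,,Cerebellar Tonsil,-27,-49,-41,positive
15,216,L.BA13.2,Insula_L,-36,7,-1,positive
16,223,L.BA19.9,Cuneus_L,-10,-83,32,positive
17,240,L.BA7.4,Parietal_Sup_L,-21,-56,57,positive
18,244,L.BA38.1,Temporal_Sup_L,-46,0,-12,positive
19,245,L.BA40.3,Inferior Parietal Lobule,-55,-38,23,positive
20,249,L.BA7.9,Precuneus_L,-3,-67,38,positive
21,255,L.BA7.7,Precuneus_L,-12,-39,64,positive
22,260,L.BA48.1,Caudate_L,-14,-15,20,positive
23,269,L.BA44.2,Insula_L,-35,5,11,positive
24,277,L.BA6.7,Supp_Motor_Area_L,-14,-2,63,positive
25,29,R.BA7.6,Superior Parietal Lobule,24,-46,61,positive
26,39,R.BA19.5,Occipital_Mid_R,43,-73,27,positive
27,45,R.BA7.3,Paracentral_Lobule_R,7,-40,62,positive
28,60,R.BA7.5,Superior Parietal Lobule,23,-66,49,positive
29,66,R.BA20.3,Cerebelum_Crus1_R,46,-53,-33,positive
30,80,R.BA7.4,Parietal_Sup_R,21,-56,55,positive
31,96,R.BA18.5,Occipital_Inf_R,23,-90,-3,positive
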