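node,subunit,ba,aal,tal_x,tal_y,tal_z,condition
1,111,R.BA44.2,Frontal_Inf_Oper_R,52,13,12,negative
2,117,R.BA19.1,Lingual_R,14,-58,0,negative
3,123,R.BA38.2,Temporal_Pole_Sup_R,37,12,-24,negative
4,134,R.BA47.2,Frontal_Inf_Orb_R,26,33,-13,negative
5,136,R.BA36.2,Precuneus_R,15,-43,3,negative
6,149,L.BA49.1,Putamen_L,-23,4,2,negative
7,154,L.BA4.1,Pretcentral_L,-57,-9,28,negative
8,158,,Pons,-4,-21,-27,negative
9,159,,Culmen_L,-44,-53,-36,negative
10,162,L.BA37.3,Cerebellum_Crus2_L,-46,-63,-23,negative
11,165,L.BA18.8,Cuneus_L,-4,-90,15,negative
12,169,L.BA45.2,Insula_L,-32,22,4,negative
13,171,L.BA23.1,Posterior Cingulate,-8,-56,21,negative
14,174,,Cerebelum_8_L,-20,-65,-40,negative
15,177,L.BA6.4,Inferior Frontal Gyrus,-41,9,31,negative
16,190,L.BA7.6,Occipital_Sup_L,-14,-68,29,negative
17,194,L.BA39.5,Angular_L,-39,-61,44,negative
18,195,L.BA40.1,Inferior Parietal Lobule,-57,-28,33,negative
19,200,L.BA10.4,Frontal_Sup_L (aal),-16,60,3,negative
20,202,L.BA19.6,Cerebellum_6_L,-26,-67,-20,negative
21,206,L.BA6.1,Inferior Frontal Gyrus,-53,1,23,negative
22,207,L.BA13.3,Insula_L,-35,-12,0,negative
23,216,L.BA13.2,Insula_L,-36,7,-1,negative
24,223,L.BA19.9,Cuneus_L,-10,-83,32,negative
25,225,L.BA10.7,Cingulum_Ant_L,-7,47,0,negative
26,238,L.BA21.3,Temporal_Mid_L,-56,-29,-13,negative
27,240,L.BA7.4,Parietal_Sup_L,-21,-56,57,negative
28,244,L.BA38.1,Temporal_Sup_L,-46,0,-12,negative
29,24,R.BA39.2,Temporal_Sup_R,48,-59,34,negative
30,251,L.BA8.2,Frontal_Sup_L,-21,25,40,negative
31,255,L.BA7.7,Precuneus_L,-12,-39,64,negative
32,267,L.BA10.6,Frontal_Sup_Medial_L,-10,57,20,negative
33,269,L.BA44.2,Insula_L,-35,5,11,negative
34,273,L.BA48.2,Caudate_L,-12,7,13,negative
35,35,R.BA37.8,Temporal_Mid_R,54,-56,0,negative
36,42,R.BA54.2,Hippocampus_R,30,-36,0,negative
37,55,R.BA31.2,Cingulum_Mid_R,9,-28,45,negative
38,75,R.BA39.4,Inferior Parietal Lobule,58,-47,24,negative
39,81,R.BA10.1,Cingulum_Ant_R,8,42,2,negative
40,86,R.BA37.7,Cerebellum_Crus1_R,47,-72,-24,negative
41,93,R.BA13.3,Insula_R,40,-6,14,negative
42,94,R.BA40.3,Parietal_Inf_R,51,-46,40,negative
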