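node,subunit,ba,aal,tal_x,tal_y,tal_z,condition
1,136,R.BA36.2,Precuneus_R,15,-43,3,neutral
2,149,L.BA49.1,Putamen_L,-23,4,2,neutral
3,154,L.BA4.1,Pretcentral_L,-57,-9,28,neutral
4,165,L.BA18.8,Cuneus_L,-4,-90,15,neutral
5,169,L.BA45.2,Insula_L,-32,22,4,neutral
6,171,L.BA23.1,Posterior Cingulate,-8,-56,21,neutral
7,174,,Cerebellum_8_L,-20,-65,-40,neutral
8,190,L.BA7.6,Occipital_Sup_L,-14,-68,29,neutral
9,198,L.BA20.1,Temporal_Inf_L,-49,-11,-26,neutral
10,206,L.BA6.1,Inferior Frontal Gyrus,-53,1,23,neutral
11,216,L.BA13.2,Insula_L,-36,7,-1,neutral
12,223,L.BA19.9,Cuneus_L,-10,-83,32,neutral
13,224,L.BA31.1,Precuneus_L,-8,-40,47,neutral
14,240,L.BA7.4,Parietal_Sup_L,-21,-56,57,neutral
15,244,L.BA38.1,Temporal_Sup_L,-46,0,-12,neutral
16,252,L.BA37.6,Fusiform_L,-32,-46,-24,neutral
17,263,L.BA48.3,Caudate_L,-11,18,2,neutral
18,266,L.BA54.1,,-28,-20,-9,neutral
19,269,L.BA44.2,Insula_L,-35,5,11,neutral
20,45,R.BA7.3,Paracentral_Lobule_R,7,-40,62,neutral
21,5,R.BA40.4,Postcentral_R,57,-20,31,neutral
22,80,R.BA7.4,Parietal_Sup_R,21,-56,55,neutral
23,90,R.BA37.9,Temporal_Inf_R,54,-48,-14,neutral
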