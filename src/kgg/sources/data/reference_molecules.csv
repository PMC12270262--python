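name,smiles,mw,logp,hbd,hba,tpsa,rotatable_bonds,molar_refractivity,heavy_atoms,total_atoms,formal_charge,aromatic_rings,qed_mw,qed_alogp,qed_hba,qed_hbd,qed_psa,qed_rotb,qed_arom,qed_alerts,qed_ref
aspirin,CC(=O)Oc1ccccc1C(=O)O,180.159,1.3101,1,4,63.6,2,44.7103,13,21,0,1,180.159,1.3101,4,1,63.6,2,1,2,0.550122
paracetamol,CC(=O)Nc1ccc(O)cc1,151.165,1.3506,2,3,49.33,1,42.4105,11,20,0,1,151.165,1.3506,2,2,49.33,1,1,1,0.595026
ibuprofen,CC(C)Cc1ccc(C(C)C(=O)O)cc1,206.285,3.0732,1,2,37.3,4,61.0348,15,33,0,1,206.285,3.0732,2,1,37.3,4,1,0,0.8216
caffeine,Cn1c(=O)c2c(ncn2C)n(C)c1=O,194.194,-1.0293,0,6,61.82,0,51.196,14,24,0,2,194.194,-1.0293,3,0,61.82,0,2,0,0.538463
levodopa,N[C@@H](Cc1ccc(O)c(O)c1)C(=O)O,197.19,0.0522,5,5,103.78,3,49.0868,14,25,0,1,197.19,0.0522,5,4,103.78,3,1,1,0.512507
carbidopa,C[C@](Cc1ccc(O)c(O)c1)(NN)C(=O)O,226.232,-0.0531,6,6,115.81,4,56.8395,16,30,0,1,226.232,-0.0531,6,5,115.81,4,1,3,0.279027
pramipexole,CCCN[C@H]1CCc2nc(N)sc2C1,211.334,1.5822,3,3,50.94,3,60.6331,14,31,0,1,211.334,1.5822,3,2,50.94,3,1,0,0.797873
ropinirole,CCCN(CCC)CCc1cccc2c1CC(=O)N2,260.381,2.8457,1,3,32.34,7,79.5017,19,43,0,1,260.381,2.8457,2,1,32.34,7,1,0,0.817332
rasagiline,C#CCN[C@H]1CCc2ccccc21,171.243,1.8967,1,1,12.03,2,54.3397,13,26,0,1,171.243,1.8967,1,1,12.03,2,1,1,0.670026
selegiline,C#CCN(C)[C@@H](C)Cc1ccccc1,187.286,2.1826,0,1,3.24,4,61.071,14,31,0,1,187.286,2.1826,1,0,3.24,4,1,1,0.653025
entacapone,CCN(CC)C(=O)/C(C#N)=C/c1cc(O)c(O)c([N+](=O)[O-])c1,305.29,1.7814,2,8,127.7,5,77.944,22,37,0,1,305.29,1.78138,6,2,127.7,5,1,5,0.280419
tolcapone,Cc1ccc(C(=O)c2cc(O)c(O)c([N+](=O)[O-])c2)cc1,273.244,2.5454,2,6,100.67,3,71.0375,20,31,0,2,273.244,2.54542,5,2,100.67,3,2,4,0.387105
amantadine,NC12CC3CC(CC(C3)C1)C2,151.253,1.9139,2,1,26.02,0,45.0904,11,28,0,0,151.253,1.9139,1,1,26.02,0,0,0,0.562066
apomorphine,CN1CCc2cccc3c2[C@H]1Cc1ccc(O)c(O)c1-3,267.328,2.8499,2,3,43.7,0,77.9866,20,37,0,2,267.328,2.8499,3,2,43.7,0,2,1,0.721339
benserazide,NC(CO)C(=O)NNCc1cc(O)c(O)c(O)c1,257.246,-1.7562,8,8,148.07,5,61.48,18,33,0,1,257.246,-1.7562,7,7,148.07,5,1,2,0.244008
bromocriptine,CC(C)C[C@H]1C(=O)N2CCC[C@H]2[C@]2(O)O[C@](NC(=O)[C@@H]3C=C4c5cccc6[nH]c(Br)c(c56)C[C@H]4N(C)C3)(C(C)C)C(=O)N12,654.606,3.1928,3,10,118.21,5,164.1582,43,83,0,2,654.606,3.1928,6,3,118.21,5,2,0,0.456327
istradefylline,CCn1c(=O)c2c(nc(/C=C/c3ccc(OC)c(OC)c3)n2C)n(CC)c1=O,384.436,2.1241,0,8,80.28,6,109.056,28,52,0,3,384.436,2.1241,5,0,80.28,6,3,0,0.650379
safinamide,C[C@H](NCc1ccc(OCc2cccc(F)c2)cc1)C(N)=O,302.349,2.3681,3,4,64.35,7,82.6701,22,41,0,2,302.349,2.3681,3,2,64.35,7,2,0,0.825046
trihexyphenidyl,OC(CCN1CCCCC1)(c1ccccc1)C1CCCCC1,301.474,4.3305,1,2,23.47,5,91.8218,22,53,0,1,301.474,4.3305,2,1,23.47,5,1,0,0.87471
biperiden,OC(CCN1CCCCC1)(c1ccccc1)C1CC2C=CC1C2,311.469,3.9624,1,2,23.47,5,94.0908,23,52,0,1,311.469,3.9624,2,1,23.47,5,1,1,0.832019
donepezil,COc1cc2c(cc1OC)C(=O)C(CC1CCN(Cc3ccccc3)CC1)C2,379.5,4.3611,0,4,38.77,6,110.1305,28,57,0,2,379.5,4.3611,4,0,38.77,6,2,0,0.747461
memantine,CC12CC3CC(C)(C1)CC(N)(C3)C2,179.307,2.6941,2,1,26.02,0,54.3244,13,34,0,0,179.307,2.6941,1,1,26.02,0,0,0,0.607647
rivastigmine,CCN(C)C(=O)Oc1cccc([C@H](C)N(C)C)c1,250.342,2.7597,0,4,32.78,4,72.872,18,40,0,1,250.342,2.7597,3,0,32.78,4,1,0,0.823422
galantamine,COc1ccc2c3c1O[C@H]1C[C@@H](O)C=C[C@@]31CCN(C)C2,287.359,1.8503,1,4,41.93,1,79.8028,21,42,0,1,287.359,1.8503,4,1,41.93,1,1,1,0.800524
fluoxetine,CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1,309.331,4.435,1,2,21.26,6,79.7987,22,40,0,2,309.331,4.435,2,1,21.26,6,2,0,0.851796
sertraline,CN[C@H]1CC[C@@H](c2ccc(Cl)c(Cl)c2)c2ccccc21,306.236,5.1796,1,1,12.03,2,85.7817,20,37,0,2,306.236,5.1796,1,1,12.03,2,2,0,0.805861
citalopram,CN(C)CCCC1(c2ccc(F)cc2)OCc2cc(C#N)ccc21,324.399,3.813,0,3,36.26,5,90.914,24,45,0,2,324.399,3.81298,3,0,36.26,5,2,0,0.838867
venlafaxine,COc1ccc(C(CN(C)C)C2(O)CCCCC2)cc1,277.408,3.0356,1,3,32.7,5,82.3238,20,47,0,1,277.408,3.0356,3,1,32.7,5,1,0,0.897682
bupropion,CC(NC(C)(C)C)C(=O)c1cccc(Cl)c1,239.746,3.2993,1,2,29.1,3,68.1332,16,34,0,1,239.746,3.2993,2,1,29.1,3,1,1,0.820494
duloxetine,CNCC[C@@H](Oc1cccc2ccccc12)c1cccs1,297.423,4.6309,1,2,21.26,6,90.1797,21,40,0,3,297.423,4.6309,2,1,21.26,6,3,0,0.715924
mirtazapine,CN1CCN2c3ccccc3Cc3ccccc3C2C1,264.372,3.0839,0,2,6.48,0,83.274,20,40,0,2,264.372,3.0839,2,0,6.48,0,2,0,0.721259
trazodone,O=c1n(CCCN2CCN(c3cccc(Cl)c3)CC2)nc2ccccn12,371.872,2.3617,0,6,45.78,5,104.174,26,48,0,3,371.872,2.3617,4,0,45.78,5,3,0,0.690401
amitriptyline,CN(C)CCC=C1c2ccccc2CCc2ccccc21,277.411,4.1686,0,1,3.24,3,90.542,21,44,0,2,277.411,4.1686,1,0,3.24,3,2,0,0.813678
imipramine,CN(C)CCCN1c2ccccc2CCc2ccccc21,280.415,3.875,0,2,6.48,4,90.469,21,45,0,2,280.415,3.875,2,0,6.48,4,2,0,0.838462
quetiapine,OCCOCCN1CCN(C2=Nc3ccccc3Sc3ccccc32)CC1,383.517,2.856,1,5,48.3,5,109.1218,27,52,0,2,383.517,2.856,5,1,48.3,5,2,1,0.80487
olanzapine,Cc1cc2c(s1)Nc1ccccc1N=C2N1CCN(C)CC1,312.442,3.4392,1,4,30.87,0,94.0477,22,42,0,2,312.442,3.43922,3,1,30.87,0,2,0,0.808256
risperidone,Cc1nc2n(c1CCN1CCC(c3noc4cc(F)ccc34)CC1)CCCC2=O,396.466,3.8704,0,6,64.16,4,106.6145,29,54,0,3,396.466,3.87042,5,0,64.16,4,3,0,0.66986
aripiprazole,O=C1CCc2ccc(OCCCCN3CCN(c4cccc(Cl)c4Cl)CC3)cc2N1,448.394,4.8593,1,5,44.81,7,123.2367,30,57,0,2,448.394,4.8593,4,1,44.81,7,2,1,0.61498
haloperidol,O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1,375.871,4.4256,1,3,40.54,6,100.9873,26,49,0,2,375.871,4.4256,3,1,40.54,6,2,1,0.759345
clozapine,CN1CCN(C2=Nc3cc(Cl)ccc3Nc3ccccc32)CC1,326.831,3.7227,1,4,30.87,0,96.4437,23,42,0,2,326.831,3.7227,3,1,30.87,0,2,0,0.800122
tetrabenazine,COc1cc2c(cc1OC)C1CC(C(=O)C2)C(CC(C)C)CN1C,331.456,3.4841,0,4,38.77,4,94.68,24,53,0,1,331.456,3.4841,4,0,38.77,4,1,0,0.846533
metformin,CN(C)C(=N)NC(=N)N,129.167,-1.0342,5,5,88.99,0,36.4635,9,20,0,0,129.167,-1.03416,3,4,88.99,0,0,2,0.248785
atorvastatin,CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1CC[C@@H](O)C[C@@H](O)CC(=O)O,558.65,6.3136,4,7,111.79,12,157.2466,41,76,0,4,558.65,6.3136,5,4,111.79,12,4,0,0.16276
warfarin,CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O,308.333,3.6096,1,4,67.51,4,87.7318,23,39,0,3,308.333,3.6096,4,1,67.51,4,3,1,0.747626
lisinopril,NCCCC[C@H](N[C@@H](CCc1ccccc1)C(=O)O)C(=O)N1CCC[C@H]1C(=O)O,405.495,1.2352,5,8,132.96,12,108.3867,29,60,0,1,405.495,1.2352,7,4,132.96,12,1,1,0.384488
omeprazole,COc1ccc2nc(S(=O)Cc3ncc(C)c(OC)c3C)[nH]c2c1,345.424,2.8997,1,6,77.1,5,93.0211,24,43,0,3,345.424,2.89974,5,1,77.1,5,3,0,0.769239
simvastatin,CCC(C)(C)C(=O)O[C@H]1C[C@@H](C)C=C2C=C[C@H](C)[C@H](CC[C@@H]3C[C@@H](O)CC(=O)O3)[C@@H]21,418.574,4.5856,1,5,72.83,6,115.4548,30,68,0,0,418.574,4.5856,5,1,72.83,6,0,1,0.639062
propranolol,CC(C)NCC(O)COc1cccc2ccccc12,259.349,2.5775,2,3,41.49,6,78.5885,19,40,0,2,259.349,2.5775,3,2,41.49,6,2,0,0.837506
atenolol,CC(C)NCC(O)COc1ccc(CC(N)=O)cc1,266.341,0.4521,4,5,84.58,8,73.9809,19,41,0,1,266.341,0.4521,4,3,84.58,8,1,0,0.637674
ethanol,CCO,46.069,-0.0014,1,1,20.23,0,12.7598,3,9,0,0,46.069,-0.0014,1,1,20.23,0,0,0,0.406808
nicotine,CN1CCC[C@H]1c1cccnc1,162.236,1.8483,0,2,16.13,1,48.842,12,26,0,1,162.236,1.8483,2,0,16.13,1,1,0,0.626152
morphine,CN1CC[C@]23c4c5ccc(O)c4O[C@H]2[C@@H](O)C=C[C@H]3[C@H]1C5,285.343,1.1981,2,4,52.93,0,77.5766,21,40,0,1,285.343,1.1981,4,2,52.93,0,1,1,0.703347
penicillin-g,CC1(C)S[C@@H]2[C@H](NC(=O)Cc3ccccc3)C(=O)N2[C@H]1C(=O)O,334.397,0.8608,2,6,86.71,4,85.8045,23,41,0,1,334.397,0.8608,5,2,86.71,4,1,1,0.797763
doxycycline,C[C@@H]1c2cccc(O)c2C(=O)C2=C(O)[C@]3(O)C(=O)C(C(N)=O)=C(O)[C@@H](N(C)C)[C@@H]3[C@@H](O)[C@H]21,444.44,-0.3476,7,10,181.62,2,109.7749,32,56,0,1,444.44,-0.3476,9,6,181.62,2,1,1,0.332217
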