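id,r1,r2,r3,ic50_nM,pic50
A0,H,H,H,11.2,7.951
A1,H,H,CH3CO,128.4,6.891
A2,H,H,CH3CH2CO,98.1,7.008
A3,H,H,CH3CH2CH2CO,85.6,7.068
A4,H,H,PhCO,52.4,7.281
A5,H,H,p-Cl-PhCO,31.8,7.498
A6,H,H,"2,3,4-(OCH3)3-PhCO",259.5,6.586
A7,H,H,PhCH2CH2CO,43.6,7.361
A8,H,H,PhCH=CHCO,5.2,8.284
A9,H,H,p-CH3O-Ph-CH=CHCO,12.3,7.910
A10,H,H,"3,4-(OCH3)2-PhCH=CHCO",13.1,7.883
B0,H,CH3,H,439.8,6.357
B1,H,CH3,CH3CO,316.4,6.500
B2,H,CH3,CH3CH2CO,280.2,6.553
B3,H,CH3,CH3CH2CH2CO,195,6.710
B4,H,CH3,PhCO,109.9,6.959
B5,H,CH3,p-Cl-PhCO,42.8,7.369
B6,H,CH3,"2,3,4-(OCH3)3-PhCO",562.6,6.250
B7,H,CH3,PhCH2CH2CO,73.4,7.134
B8,H,CH3,PhCH=CHCO,39.1,7.408
B9,H,CH3,p-CH3O-Ph-CH=CHCO,7.8,8.108
B10,H,CH3,"3,4-(OCH3)2-PhCH=CHCO",121.3,6.916
C1,CH3,CH3,CH3CO,320.2,6.495
C2,CH3,CH3,CH3CH2CO,293.4,6.533
C3,CH3,CH3,CH3CH2CH2CO,221.1,6.655
C4,CH3,CH3,PhCO,201.2,6.696
C5,CH3,CH3,p-Cl-PhCO,111.8,6.952
C7,CH3,CH3,PhCH2CH2CO,168.3,6.774
C8,CH3,CH3,PhCH=CHCO,86.5,7.063
C9,CH3,CH3,p-CH3O-Ph-CH=CHCO,28.7,7.542
C10,CH3,CH3,"3,4-(OCH3)2-PhCH=CHCO",9.7,8.013
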