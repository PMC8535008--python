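patient,age,sex,healthy_stomach_pct,healthy_esophagus_pct,cancer_pct,tumor_type,tissue_location,t_classification
13,83,m,39.65,36.16,24.19,not determined,G-E junction,ypT0
14,71,m,0,96.38,3.62,AC,G-E junction,ypT3
15,72,m,31.77,61.88,6.35,AC,G-E junction,ypT1b
16,67,m,60.59,31.11,8.30,AC,G-E junction,ypT1b
17,73,m,32.71,48.31,18.98,AC,G-E junction,ypT0
18,67,m,6.79,87.02,6.20,AC,G-E junction,ypT3
19,54,m,36.66,62.15,1.19,AC,G-E junction,ypT1b
20,65,f,99.13,0,0.87,AC,G-E junction,pT1b
21,56,m,61.64,16.31,22.06,AC,G-E junction,ypT2
22,60,m,30.34,67.09,2.57,AC,G-E junction,ypT0
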