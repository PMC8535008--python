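patient,age,sex,healthy_pct,cancer_pct,tissue_location,t_classification,grade
1,67,f,93.57,6.43,colon,pT3b,G2
2,68,m,100,0,colon,adenoma,
3,52,m,91.27,8.73,colon,pT2,G2
4,67,f,98.68,1.32,colorectal,pT2,G2
5,80,m,92.55,7.45,colorectal,pT2,G2
6,80,m,100,0,colon,adenoma,
7,81,m,56.16,43.84,colorectal,ypT3,G1
8,66,m,97.12,2.88,colorectal,rpT2,G2
9,66,m,94.62,5.38,colorectal,ypT2,G1
10,60,m,90.50,9.50,sigma,ypT3,G3
11,79,f,89.63,10.37,ascending colon,pT3,G2
12,59,m,96.59,3.41,colon ascendens,pT2,G2
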