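patient,rbf_svm,mlp,cnn3d,rbf_svm_combined,mlp_combined,cnn3d_combined
1,0.97,0.98,1.0,0.98,0.98,0.99
2,,,,,,
3,0.93,0.96,0.96,0.93,0.97,0.85
4,0.98,1.0,0.99,0.98,1.0,0.87
5,0.86,0.87,0.95,0.87,0.93,0.94
6,,,,,,
7,0.69,0.66,0.89,0.78,0.87,0.72
8,0.56,0.77,0.93,0.67,0.75,0.96
9,0.95,0.90,0.99,0.94,0.74,0.99
10,0.91,0.92,0.77,0.78,0.68,0.89
11,0.98,0.98,0.93,0.98,0.99,0.98
12,0.94,0.88,0.88,0.89,0.90,1.0
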