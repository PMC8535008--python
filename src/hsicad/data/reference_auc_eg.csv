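patient,rbf_svm,mlp,cnn3d,rbf_svm_combined,mlp_combined,cnn3d_combined
13,0.96,0.96,0.91,0.98,0.99,0.99
14,0.81,0.85,0.99,0.99,0.98,0.98
15,0.91,0.92,0.92,0.87,0.92,0.95
16,0.91,0.87,0.98,0.91,0.96,0.96
17,0.59,0.67,0.89,0.73,0.48,0.89
18,0.53,0.47,0.90,0.80,0.87,0.85
19,0.81,0.93,0.93,0.95,0.99,0.97
20,0.68,0.55,0.71,0.85,0.77,0.79
21,0.91,0.94,0.92,0.99,1.0,0.96
22,0.80,0.79,0.99,0.95,0.98,0.98
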