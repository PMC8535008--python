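patient,direction,mlp,cnn3d
1,eg_to_colon,0.64,0.96
2,eg_to_colon,,
3,eg_to_colon,0.34,0.59
4,eg_to_colon,0.67,0.61
5,eg_to_colon,0.64,0.90
6,eg_to_colon,,
7,eg_to_colon,0.79,0.43
8,eg_to_colon,0.59,0.89
9,eg_to_colon,0.57,0.92
10,eg_to_colon,0.87,0.58
11,eg_to_colon,0.65,0.98
12,eg_to_colon,0.91,0.96
13,colon_to_eg,0.80,0.99
14,colon_to_eg,0.75,0.77
15,colon_to_eg,0.91,0.83
16,colon_to_eg,0.84,0.79
17,colon_to_eg,0.72,0.68
18,colon_to_eg,0.48,0.78
19,colon_to_eg,0.82,0.99
20,colon_to_eg,0.49,0.90
21,colon_to_eg,0.84,0.95
22,colon_to_eg,0.71,0.94
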