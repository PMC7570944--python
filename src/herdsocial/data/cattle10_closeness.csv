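,1,2,3,4,5,6,7,8,9,10
1,0,6.06,3.61,5.28,4.45,4.11,4.32,5.79,6.19,5.19
2,6.43,0,5.29,4.92,3.52,3.65,5.81,5.34,4.90,5.15
3,5.46,5.70,0,4.69,5.19,4.24,4.12,5.81,4.43,5.36
4,6.68,5.27,4.94,0,3.62,4.10,6.48,5.23,4.58,4.10
5,6.17,4.34,5.26,4.35,0,3.99,6.69,4.36,4.79,5.05
6,6.10,4.55,4.71,4.72,3.98,0,5.59,5.27,5.28,4.79
7,4.86,5.59,3.28,4.62,5.13,3.55,0,6.75,5.40,5.83
8,6.62,5.78,5.29,4.99,3.63,4.79,7.31,0,3.52,3.06
9,7.39,5.29,4.65,4.94,4.42,4.81,6.39,3.40,0,3.69
10,6.51,5.79,5.61,4.48,4.55,4.65,6.91,2.99,3.49,0
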