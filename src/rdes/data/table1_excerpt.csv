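Well,Sample,Sample type,Target,Target type,Dye,Cq,1,2,3,4,…,42,43,44,45
A1,Embryo_1,unkn,SCX,toi,SYBR,33.2,1.30,1.28,1.28,1.27,…,15.10,15.29,15.34,15.43
A2,Embryo_2,unkn,SCX,toi,SYBR,33.8,1.28,1.32,1.30,1.26,…,13.65,14.02,14.16,14.21
A3,Embryo_3,unkn,SCX,toi,SYBR,32.0,1.53,1.53,1.54,1.51,…,15.44,15.62,15.79,15.87
A4,Embryo_4,unkn,SCX,toi,SYBR,34.3,1.44,1.44,1.43,1.42,…,13.81,14.29,14.64,14.86
A5,Embryo_5,unkn,SCX,toi,SYBR,31.9,1.45,1.45,1.43,1.40,…,15.42,15.70,15.74,15.95
A6,Embryo_6,unkn,SCX,toi,SYBR,32.6,1.47,1.47,1.47,1.44,…,15.02,15.14,15.18,15.21
A7,Embryo_7,unkn,SCX,toi,SYBR,33.1,1.47,1.48,1.46,1.45,…,18.54,18.99,19.17,19.34
A8,Embryo_8,unkn,SCX,toi,SYBR,31.7,1.37,1.34,1.34,1.30,…,18.15,18.30,18.44,18.44
H9,Adult_9,unkn,cTNI,toi,SYBR,19.4,1.51,1.48,1.49,1.48,…,19.01,19.06,18.99,19.02
H10,Adult_10,unkn,cTNI,toi,SYBR,19.8,1.41,1.43,1.44,1.49,…,16.80,16.83,16.78,16.84
H11,Adult_11,unkn,cTNI,toi,SYBR,19.4,1.43,1.44,1.48,1.47,…,16.13,16.09,16.03,16.04
H12,Adult_12,unkn,cTNI,toi,SYBR,19.0,1.52,1.50,1.53,1.50,…,17.35,17.29,17.27,17.29
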