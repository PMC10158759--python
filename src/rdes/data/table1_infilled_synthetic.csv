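Well,Sample,Sample type,Target,Target type,Dye,Cq,1,2,3,4,5,6,7,8,9,10,11,12,13,14,15,16,17,18,19,20,21,22,23,24,25,26,27,28,29,30,31,32,33,34,35,36,37,38,39,40,41,42,43,44,45
A1,Embryo_1,unkn,SCX,toi,SYBR,33.2,1.3,1.28,1.28,1.27,1.28,1.28,1.28,1.28,1.28,1.28,1.28,1.28,1.28,1.28,1.28,1.28,1.28,1.28,1.28,1.28,1.28,1.28,1.28,1.29,1.29,1.3,1.31,1.34,1.39,1.48,1.66,1.98,2.55,3.51,4.99,6.99,9.24,11.34,12.96,14.04,14.69,15.1,15.29,15.34,15.43
A2,Embryo_2,unkn,SCX,toi,SYBR,33.8,1.28,1.32,1.3,1.26,1.29,1.29,1.29,1.29,1.29,1.29,1.29,1.29,1.29,1.29,1.29,1.29,1.29,1.29,1.29,1.29,1.29,1.29,1.29,1.29,1.3,1.3,1.31,1.32,1.36,1.41,1.53,1.73,2.1,2.75,3.81,5.36,7.33,9.38,11.15,12.42,13.24,13.65,14.02,14.16,14.21
A3,Embryo_3,unkn,SCX,toi,SYBR,32,1.53,1.53,1.54,1.51,1.53,1.53,1.53,1.53,1.53,1.53,1.53,1.53,1.53,1.53,1.53,1.53,1.53,1.53,1.53,1.53,1.53,1.53,1.53,1.54,1.55,1.56,1.59,1.65,1.76,1.96,2.32,2.96,4.03,5.64,7.74,10.03,12.07,13.59,14.59,15.18,15.51,15.44,15.62,15.79,15.87
A4,Embryo_4,unkn,SCX,toi,SYBR,34.3,1.44,1.44,1.43,1.42,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.44,1.44,1.45,1.46,1.48,1.53,1.61,1.77,2.06,2.57,3.44,4.8,6.66,8.81,10.84,12.43,13.51,13.81,14.29,14.64,14.86
A5,Embryo_5,unkn,SCX,toi,SYBR,31.9,1.45,1.45,1.43,1.4,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.43,1.44,1.44,1.44,1.45,1.47,1.5,1.56,1.68,1.89,2.29,2.97,4.11,5.79,7.95,10.26,12.28,13.77,14.72,15.29,15.61,15.42,15.7,15.74,15.95
A6,Embryo_6,unkn,SCX,toi,SYBR,32.6,1.47,1.47,1.47,1.44,1.46,1.46,1.46,1.46,1.46,1.46,1.46,1.46,1.46,1.46,1.46,1.46,1.46,1.46,1.46,1.46,1.46,1.46,1.47,1.47,1.47,1.48,1.5,1.54,1.61,1.75,1.99,2.43,3.19,4.42,6.17,8.31,10.45,12.23,13.48,14.26,14.71,15.02,15.14,15.18,15.21
A7,Embryo_7,unkn,SCX,toi,SYBR,33.1,1.47,1.48,1.46,1.45,1.47,1.47,1.47,1.47,1.47,1.47,1.47,1.47,1.47,1.47,1.47,1.47,1.47,1.47,1.47,1.47,1.47,1.47,1.47,1.47,1.48,1.49,1.5,1.54,1.61,1.73,1.97,2.4,3.16,4.43,6.37,8.95,11.8,14.4,16.38,17.68,18.46,18.54,18.99,19.17,19.34
A8,Embryo_8,unkn,SCX,toi,SYBR,31.7,1.37,1.34,1.34,1.3,1.34,1.34,1.34,1.34,1.34,1.34,1.34,1.34,1.34,1.34,1.34,1.34,1.34,1.34,1.34,1.34,1.34,1.34,1.34,1.35,1.36,1.39,1.43,1.51,1.67,1.95,2.47,3.37,4.83,6.94,9.57,12.25,14.52,16.14,17.16,17.75,18.08,18.15,18.3,18.44,18.44
H9,Adult_9,unkn,cTNI,toi,SYBR,19.4,1.51,1.48,1.49,1.48,1.49,1.49,1.49,1.49,1.49,1.49,1.5,1.51,1.52,1.55,1.6,1.71,1.9,2.25,2.88,3.95,5.64,7.99,10.75,13.42,15.54,17,17.9,18.41,18.69,18.85,18.93,18.97,18.99,19.01,19.01,19.02,19.02,19.02,19.02,19.02,19.02,19.01,19.06,18.99,19.02
H10,Adult_10,unkn,cTNI,toi,SYBR,19.8,1.41,1.43,1.44,1.49,1.44,1.44,1.44,1.44,1.44,1.45,1.45,1.45,1.46,1.48,1.52,1.59,1.72,1.96,2.4,3.17,4.42,6.27,8.59,11.02,13.11,14.62,15.59,16.15,16.47,16.64,16.74,16.79,16.81,16.82,16.83,16.84,16.84,16.84,16.84,16.84,16.84,16.8,16.83,16.78,16.84
H11,Adult_11,unkn,cTNI,toi,SYBR,19.4,1.43,1.44,1.48,1.47,1.46,1.46,1.46,1.46,1.46,1.46,1.46,1.47,1.48,1.51,1.55,1.64,1.79,2.09,2.61,3.5,4.91,6.86,9.16,11.38,13.15,14.36,15.1,15.53,15.77,15.9,15.96,16,16.02,16.03,16.03,16.04,16.04,16.04,16.04,16.04,16.04,16.13,16.09,16.03,16.04
H12,Adult_12,unkn,cTNI,toi,SYBR,19,1.52,1.5,1.53,1.5,1.51,1.51,1.51,1.51,1.52,1.52,1.52,1.53,1.55,1.58,1.65,1.76,1.98,2.38,3.09,4.26,6.03,8.34,10.84,13.08,14.76,15.85,16.5,16.86,17.06,17.17,17.23,17.26,17.27,17.28,17.29,17.29,17.29,17.29,17.29,17.29,17.29,17.35,17.29,17.27,17.29
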