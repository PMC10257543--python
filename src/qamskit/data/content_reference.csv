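sample,method,eriocitrin,neoeriocitrin,narirutin,naringin,hesperidin,neohesperidin,hesperidin-7-O-glucoside,poncirin,naringenin,hesperetin
F1,ESM,4.04,2.62,3.76,28.42,2.15,45.16,0.16,3.38,0.17,0.06
F1,QAMS,4.11,2.61,3.76,,2.17,46.06,0.16,3.43,0.17,0.06
F2,ESM,3.13,1.66,3.46,20.38,3.00,37.85,9.66,2.49,0.74,0.52
F2,QAMS,3.14,1.64,3.45,,3.05,38.60,9.79,2.50,0.75,0.52
F3,ESM,2.94,0.65,3.51,17.03,1.87,27.43,14.05,1.58,1.39,1.19
F3,QAMS,2.94,0.64,3.50,,1.89,27.49,14.17,1.60,1.37,1.21
F4,ESM,2.47,0.87,3.48,14.94,1.74,36.76,5.22,2.18,1.28,1.21
F4,QAMS,2.46,0.88,3.47,,1.74,37.49,5.26,2.17,1.26,1.23
F5,ESM,2.48,0.72,3.38,10.25,2.58,24.37,4.37,1.47,1.17,1.02
F5,QAMS,2.46,0.71,3.37,,2.60,24.21,4.38,1.45,1.15,1.03
S1,ESM,3.82,0.94,3.77,18.02,2.31,40.50,6.32,2.99,0.95,0.98
S1,QAMS,3.88,0.95,3.78,,2.30,41.11,6.40,3.01,0.96,0.98
S2,ESM,3.61,0.94,4.43,24.08,2.23,39.00,10.05,2.57,1.78,1.45
S2,QAMS,3.66,0.94,4.47,,2.22,39.52,10.18,2.57,1.81,1.46
S3,ESM,3.08,0.89,3.39,18.58,2.01,34.86,6.67,2.34,0.97,0.80
S3,QAMS,3.09,0.89,3.38,,1.98,35.12,6.69,2.32,0.98,0.80
S4,ESM,2.49,0.77,3.53,18.89,2.23,27.38,5.15,2.45,1.17,0.78
S4,QAMS,2.47,0.75,3.52,,2.21,27.18,5.18,2.45,1.18,0.79
S5,ESM,3.46,0.90,3.58,20.93,2.05,41.63,4.22,2.85,0.92,0.78
S5,QAMS,3.50,0.90,3.57,,2.02,42.31,4.22,2.86,0.93,0.79
T1,ESM,3.29,0.99,4.18,22.99,2.25,42.31,0.16,3.45,0.23,0.17
T1,QAMS,3.32,1.01,4.21,,2.24,43.04,0.16,3.48,0.23,0.18
T2,ESM,3.21,1.06,3.82,22.31,2.68,35.63,3.07,2.49,0.70,0.45
T2,QAMS,3.23,1.08,3.82,,2.71,35.94,3.08,2.48,0.71,0.45
T3,ESM,3.13,1.68,3.46,20.38,3.00,37.85,5.22,2.49,0.74,0.52
T3,QAMS,3.14,1.69,3.45,,3.06,38.30,5.26,2.49,0.75,0.52
T4,ESM,2.57,0.67,2.99,13.31,2.36,33.60,4.19,2.51,0.67,0.50
T4,QAMS,2.55,0.67,2.96,,2.36,33.79,4.19,2.51,0.67,0.50
T5,ESM,2.70,0.81,3.30,15.05,2.72,34.13,1.56,2.56,0.51,0.40
T5,QAMS,2.69,0.80,3.28,,2.75,34.34,1.57,2.55,0.51,0.40
H1,ESM,3.73,1.02,5.12,21.29,3.14,39.10,1.49,2.63,0.73,0.53
H1,QAMS,3.78,1.04,5.19,,3.18,39.62,1.49,2.63,0.74,0.53
H2,ESM,3.66,0.99,4.73,20.43,3.10,39.25,1.71,2.63,0.73,0.68
H2,QAMS,3.71,1.00,4.79,,3.14,39.79,1.73,2.64,0.74,0.68
H3,ESM,3.44,0.94,4.25,20.43,2.70,36.96,2.78,2.62,0.78,0.83
H3,QAMS,3.48,0.94,4.28,,2.70,37.35,2.82,2.62,0.79,0.85
H4,ESM,3.24,0.91,3.92,19.23,2.54,35.77,5.11,2.34,1.64,1.21
H4,QAMS,3.26,0.91,3.93,,2.53,36.09,5.15,2.33,1.67,1.19
H5,ESM,2.92,0.91,3.70,15.10,2.39,35.35,7.75,2.16,2.46,2.87
H5,QAMS,2.93,0.91,3.70,,2.36,35.64,7.88,2.14,2.50,2.88
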