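analyte,vol_1.0,vol_1.5,vol_2.0,vol_2.5,vol_3.0,mean_printed,rsd_printed
eriocitrin,0.254,0.252,0.252,0.255,0.256,0.254,0.76
neoeriocitrin,0.327,0.330,0.321,0.343,0.343,0.333,2.93
narirutin,0.246,0.246,0.241,0.243,0.242,0.243,0.92
naringin,1.000,1.000,1.000,1.000,1.000,1.000,0.00
hesperidin,0.532,0.527,0.523,0.522,0.521,0.525,0.85
neohesperidin,0.627,0.627,0.628,0.629,0.629,0.628,0.11
hesperidin-7-O-glucoside,0.361,0.356,0.351,0.349,0.348,0.353,1.59
poncirin,0.267,0.271,0.274,0.275,0.276,0.273,1.29
naringenin,0.553,0.560,0.565,0.568,0.569,0.563,1.18
hesperetin,0.465,0.479,0.486,0.490,0.493,0.482,2.25
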