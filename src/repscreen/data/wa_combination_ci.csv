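cell_line,wa_um,partner_um,partner,ci_mean,ci_sd
A549,0.5,5,pemetrexed,1.15,0.17
A549,0.5,10,pemetrexed,1.23,0.05
A549,0.5,20,pemetrexed,1.11,0.32
A549,0.5,5,cisplatin,1.39,0.12
A549,0.5,10,cisplatin,0.83,0.03
A549,0.5,20,cisplatin,0.86,0.04
A549,0.5,5,gemcitabine,0.63,0.04
A549,0.5,10,gemcitabine,0.72,0.15
A549,0.5,20,gemcitabine,0.56,0.11
CL141,0.5,5,pemetrexed,0.56,0.01
CL141,0.5,10,pemetrexed,0.60,0.02
CL141,0.5,20,pemetrexed,0.69,0.12
CL141,0.5,5,cisplatin,0.51,0.01
CL141,0.5,10,cisplatin,0.62,0.03
CL141,0.5,20,cisplatin,0.83,0.09
CL141,0.5,5,gemcitabine,0.97,0.09
CL141,0.5,10,gemcitabine,0.76,0.05
CL141,0.5,20,gemcitabine,0.73,0.09
CL152,0.5,5,pemetrexed,0.59,0.03
CL152,0.5,10,pemetrexed,0.57,0.05
CL152,0.5,20,pemetrexed,0.53,0.05
CL152,0.5,5,cisplatin,0.60,0.02
CL152,0.5,10,cisplatin,0.68,0.03
CL152,0.5,20,cisplatin,1.00,0.05
CL152,0.5,5,gemcitabine,1.15,0.02
CL152,0.5,10,gemcitabine,0.84,0.06
CL152,0.5,20,gemcitabine,0.85,0.09
H1299,0.5,5,pemetrexed,0.73,0.05
H1299,0.5,10,pemetrexed,0.46,0.02
H1299,0.5,20,pemetrexed,0.47,0.02
H1299,0.5,5,cisplatin,0.35,0.02
H1299,0.5,10,cisplatin,0.31,0.05
H1299,0.5,20,cisplatin,0.18,0.04
H1299,0.5,5,gemcitabine,1.08,0.09
H1299,0.5,10,gemcitabine,0.72,0.11
H1299,0.5,20,gemcitabine,0.72,0.12
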