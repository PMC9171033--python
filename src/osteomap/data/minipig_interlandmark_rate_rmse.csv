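pair,T1-T2,T2-T3,T3-T4,T4-T5,T5-T6,T6-T7,T7-T8,T8-T9,T9-T10,T10-T11,T11-T12,Mean,SD
MF1-Go,0.04,0.03,0.05,0.04,0.04,0.03,0.04,0.05,0.10,0.02,0.03,0.04,0.02
Go-MF3,0.04,0.05,0.07,0.05,0.05,0.04,0.08,0.03,0.10,0.05,0.03,0.05,0.02
Cr-Cd-lat,0.10,0.03,0.09,0.05,0.02,0.10,0.06,0.09,0.07,0.10,0.05,0.07,0.03
Cr-Cd-med,0.04,0.02,0.01,0.07,0.03,0.08,0.02,0.09,0.09,0.08,0.08,0.05,0.03
MF1-MF2,0.10,0.03,0.05,0.02,0.00,0.06,0.02,0.02,0.04,0.03,0.01,0.04,0.03
MF2-MF3,0.04,0.03,0.00,0.05,0.06,0.03,0.01,0.04,0.03,0.03,0.01,0.04,0.02
Go-Cr,0.03,0.03,0.04,0.06,0.02,0.03,0.02,0.09,0.08,0.06,0.11,0.05,0.03
Go-Cd-med,0.03,0.04,0.06,0.06,0.03,0.04,0.03,0.14,0.07,0.08,0.13,0.06,0.04
Go-Cd-lat,0.02,0.05,0.04,0.09,0.04,0.02,0.03,0.11,0.09,0.09,0.11,0.06,0.03
MF1-Cd-lat,0.03,0.04,0.04,0.03,0.04,0.02,0.02,0.07,0.06,0.04,0.03,0.04,0.02
MF1-Cd-med,0.02,0.03,0.02,0.02,0.03,0.01,0.01,0.08,0.05,0.06,0.01,0.03,0.02
MF1-Cr,0.03,0.04,0.02,0.02,0.03,0.01,0.02,0.06,0.04,0.03,0.00,0.03,0.02
GF-Cd-lat,0.04,0.02,0.03,0.04,0.03,0.01,0.02,0.08,0.05,0.03,0.02,0.03,0.02
GF-Cd-med,0.02,0.04,0.04,0.01,0.03,0.01,0.02,0.08,0.01,0.07,0.03,0.03,0.02
GF-Cr,0.02,0.04,0.02,0.02,0.03,0.01,0.03,0.07,0.02,0.05,0.03,0.03,0.02
inter-Go,0.04,0.00,0.01,0.04,0.01,0.04,0.02,0.08,0.15,0.03,0.01,0.04,0.04
inter-Cd-lat,0.07,0.05,0.10,0.12,0.12,0.08,0.11,0.09,0.15,0.18,0.07,0.10,0.04
inter-Cr,0.13,0.02,0.04,0.04,0.03,0.04,0.07,0.08,0.03,0.06,0.16,0.06,0.04
inter-Cd-med,0.15,0.03,0.04,0.05,0.02,0.01,0.04,0.09,0.08,0.05,0.20,0.07,0.06
inter-MF3,0.14,0.04,0.08,0.01,0.01,0.02,0.06,0.10,0.10,0.13,0.08,0.07,0.05
inter-MF2,0.09,0.03,0.13,0.05,0.03,0.01,0.08,0.14,0.09,0.07,0.07,0.07,0.04
inter-MF1,0.14,0.00,0.13,0.04,0.02,0.06,0.10,0.13,0.03,0.10,0.08,0.08,0.05
Mean,0.06,0.03,0.05,0.05,0.03,0.03,0.04,0.08,0.07,0.07,0.07,,
SD,0.04,0.01,0.04,0.02,0.02,0.03,0.03,0.03,0.04,0.04,0.05,,
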