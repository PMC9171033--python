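landmark,T1,T2,T3,T4,T5,T6,T7,T8,T9,T10,T11,T12,Mean,SD
GT,0.22,0.38,0.03,0.37,0.02,0.21,0.05,0.21,0.54,0.68,0.54,0.68,0.33,0.24
R_Cd-lat,0.25,0.15,0.34,0.23,0.10,0.37,0.25,0.25,0.51,0.51,0.48,0.83,0.36,0.20
R_Cd-med,0.20,0.13,0.40,0.41,0.23,0.27,0.12,0.15,0.36,0.52,0.64,0.77,0.35,0.21
R_Cr,0.29,0.23,0.24,0.24,0.14,0.27,0.20,0.18,0.41,0.54,0.54,0.66,0.33,0.17
R_MF1,0.24,0.31,0.18,0.31,0.12,0.23,0.11,0.24,0.71,0.86,0.72,0.66,0.39,0.27
R_MF2,0.22,0.26,0.11,0.32,0.12,0.22,0.09,0.18,0.62,0.77,0.67,0.75,0.36,0.26
R_MF3,0.10,0.28,0.07,0.25,0.09,0.24,0.18,0.16,0.62,0.71,0.61,0.65,0.33,0.24
R_GF,0.15,0.26,0.08,0.43,0.06,0.26,0.07,0.30,0.62,0.75,0.62,0.62,0.35,0.25
R_Go,0.24,0.21,0.31,0.24,0.15,0.30,0.25,0.33,0.34,0.43,0.49,0.50,0.32,0.11
L_Cd-lat,0.26,0.21,0.43,0.12,0.33,0.37,0.22,0.21,0.41,0.55,0.41,0.55,0.34,0.14
L_Cd-med,0.20,0.11,0.29,0.34,0.22,0.22,0.12,0.24,0.31,0.38,0.56,0.70,0.31,0.17
L_Cr,0.19,0.22,0.20,0.17,0.32,0.23,0.09,0.25,0.39,0.46,0.52,0.68,0.31,0.17
L_MF1,0.18,0.36,0.28,0.26,0.12,0.40,0.25,0.16,0.73,0.77,0.56,0.47,0.38,0.22
L_MF2,0.16,0.25,0.10,0.23,0.10,0.30,0.17,0.21,0.69,0.85,0.79,0.80,0.39,0.30
L_MF3,0.19,0.27,0.22,0.24,0.22,0.34,0.25,0.26,0.53,0.52,0.52,0.53,0.34,0.14
L_GF,0.14,0.24,0.06,0.38,0.15,0.34,0.08,0.32,0.58,0.65,0.53,0.57,0.34,0.21
L_Go,0.27,0.19,0.19,0.28,0.44,0.37,0.31,0.38,0.38,0.37,0.46,0.75,0.37,0.15
Mean,0.21,0.24,0.21,0.28,0.17,0.29,0.17,0.24,0.51,0.61,0.57,0.66,,
SD,0.05,0.07,0.12,0.08,0.11,0.06,0.08,0.07,0.14,0.16,0.10,0.11,,
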