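region,direction,T1-T2,T2-T3,T3-T4,T4-T5,T5-T6,T6-T7,T7-T8,T8-T9,T9-T10,T10-T11,T11-T12,EnsembleMean,EnsembleSD
condyle,ap,1.92,1.53,0.72,0.61,0.95,0.58,0.61,0.61,0.54,0.47,0.42,0.81,0.48
condyle,si,1.52,1.37,0.72,0.54,0.77,0.46,0.39,0.48,0.49,0.37,0.48,0.69,0.39
condyle,ml,1.04,1.23,0.63,0.49,0.73,0.40,0.41,0.38,0.49,0.30,0.31,0.58,0.30
posterior_ramus,ap,1.55,1.58,0.76,0.64,0.74,0.57,0.63,0.53,0.46,0.42,0.39,0.75,0.42
posterior_ramus,si,1.41,1.19,0.64,0.45,0.58,0.42,0.43,0.38,0.46,0.41,0.43,0.62,0.35
posterior_ramus,ml,1.16,0.95,0.51,0.47,0.60,0.44,0.32,0.36,0.39,0.30,0.32,0.53,0.28
anterior_ramus,ap,1.43,1.50,0.70,0.60,0.77,0.58,0.58,0.54,0.46,0.43,0.42,0.73,0.38
anterior_ramus,si,1.36,1.21,0.65,0.48,0.66,0.47,0.46,0.36,0.43,0.38,0.50,0.63,0.34
anterior_ramus,ml,1.06,1.12,0.41,0.42,0.63,0.42,0.30,0.30,0.40,0.31,0.31,0.52,0.30
posterior_corpus,ap,0.54,0.88,0.65,0.61,0.81,0.44,0.75,0.50,0.50,0.42,0.49,0.60,0.16
posterior_corpus,si,0.45,0.55,0.54,0.59,0.77,0.40,0.50,0.45,0.59,0.47,0.50,0.53,0.10
posterior_corpus,ml,0.36,0.53,0.42,0.54,0.62,0.45,0.58,0.50,0.51,0.40,0.36,0.48,0.09
middle_corpus,ap,0.49,0.68,0.32,0.33,0.35,0.42,0.34,0.29,0.34,0.27,0.42,0.39,0.12
middle_corpus,si,0.56,0.60,0.32,0.41,0.40,0.42,0.33,0.30,0.29,0.29,0.37,0.39,0.11
middle_corpus,ml,0.37,0.45,0.25,0.33,0.32,0.41,0.27,0.30,0.27,0.23,0.29,0.32,0.07
anterior_corpus,ap,0.69,0.89,0.48,0.42,0.58,0.50,0.56,0.47,0.43,0.42,0.36,0.53,0.15
anterior_corpus,si,0.57,0.71,0.43,0.33,0.46,0.40,0.41,0.37,0.43,0.36,0.44,0.45,0.11
anterior_corpus,ml,0.42,0.54,0.32,0.31,0.41,0.35,0.36,0.32,0.36,0.32,0.36,0.37,0.07
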