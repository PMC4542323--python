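label,hemisphere,region,measure,a2,a2_lo,a2_hi,c2,c2_lo,c2_hi,e2,e2_lo,e2_hi,p_A,p_C,p_AC
L-C-SA,L,C,SA,0.58,0.30,0.69,0.00,0.00,0.23,0.42,0.31,0.55,0.00,1.00,0.00
L-O-SA,L,O,SA,0.38,0.00,0.71,0.24,0.00,0.56,0.38,0.28,0.51,0.05,0.23,0.00
L-PLT-SA,L,PLT,SA,0.69,0.43,0.77,0.00,0.00,0.23,0.31,0.23,0.42,0.00,1.00,0.00
L-SP-SA,L,SP,SA,0.53,0.11,0.72,0.09,0.00,0.46,0.38,0.28,0.51,0.01,0.67,0.00
L-OF-SA,L,OF,SA,0.51,0.24,0.63,0.00,0.00,0.22,0.49,0.37,0.64,0.00,1.00,0.00
L-ST-SA,L,ST,SA,0.49,0.07,0.62,0.00,0.00,0.36,0.51,0.38,0.66,0.02,1.00,0.00
L-IP-SA,L,IP,SA,0.40,0.14,0.55,0.00,0.00,0.00,0.60,0.45,0.77,0.01,1.00,0.00
L-DMF-SA,L,DMF,SA,0.61,0.32,0.71,0.00,0.00,0.25,0.39,0.29,0.52,0.00,1.00,0.00
L-AMT-SA,L,AMT,SA,0.46,0.10,0.59,0.00,0.00,0.31,0.54,0.41,0.69,0.02,1.00,0.00
L-PRC-SA,L,PRC,SA,0.61,0.33,0.71,0.00,0.00,0.24,0.39,0.29,0.51,0.00,1.00,0.00
L-DLP-SA,L,DLP,SA,0.65,0.41,0.74,0.00,0.00,0.20,0.35,0.26,0.48,0.00,1.00,0.00
L-PRS-SA,L,PRS,SA,0.57,0.15,0.71,0.04,0.00,0.39,0.39,0.29,0.53,0.01,0.84,0.00
R-C-SA,R,C,SA,0.57,0.28,0.68,0.00,0.00,0.00,0.43,0.32,0.57,0.00,1.00,0.00
R-O-SA,R,O,SA,0.53,0.09,0.64,0.00,0.00,0.38,0.47,0.36,0.61,0.02,1.00,0.00
R-PLT-SA,R,PLT,SA,0.51,0.21,0.63,0.00,0.00,0.24,0.49,0.37,0.64,0.00,1.00,0.00
R-SP-SA,R,SP,SA,0.54,0.32,0.66,0.00,0.00,0.17,0.46,0.34,0.61,0.00,1.00,0.00
R-OF-SA,R,OF,SA,0.53,0.12,0.65,0.00,0.00,0.34,0.47,0.35,0.62,0.01,1.00,0.00
R-ST-SA,R,ST,SA,0.34,0.00,0.58,0.11,0.00,0.47,0.56,0.42,0.74,0.21,0.66,0.00
R-IP-SA,R,IP,SA,0.45,0.21,0.59,0.00,0.00,0.17,0.55,0.41,0.73,0.00,1.00,0.00
R-DMF-SA,R,DMF,SA,0.62,0.40,0.72,0.00,0.00,0.00,0.38,0.28,0.51,0.00,1.00,0.00
R-AMT-SA,R,AMT,SA,0.50,0.11,0.61,0.00,0.00,0.34,0.50,0.39,0.64,0.02,1.00,0.00
R-PRC-SA,R,PRC,SA,0.42,0.10,0.56,0.00,0.00,0.25,0.58,0.44,0.75,0.02,1.00,0.00
R-DLP-SA,R,DLP,SA,0.60,0.16,0.73,0.04,0.00,0.43,0.36,0.27,0.49,0.01,0.85,0.00
R-PRS-SA,R,PRS,SA,0.56,0.25,0.67,0.00,0.00,0.26,0.44,0.33,0.58,0.00,1.00,0.00
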