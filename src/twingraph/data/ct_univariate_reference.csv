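label,hemisphere,region,measure,a2,a2_lo,a2_hi,c2,c2_lo,c2_hi,e2,e2_lo,e2_hi,p_A,p_C,p_AC
L-C-CT,L,C,CT,0.21,0.00,0.45,0.09,0.00,0.39,0.70,0.55,0.87,0.47,0.72,0.00
L-O-CT,L,O,CT,0.34,0.00,0.66,0.22,0.00,0.56,0.44,0.33,0.59,0.14,0.35,0.00
L-PLT-CT,L,PLT,CT,0.26,0.00,0.62,0.25,0.00,0.55,0.49,0.37,0.65,0.27,0.30,0.00
L-SP-CT,L,SP,CT,0.15,0.00,0.58,0.33,0.00,0.55,0.52,0.40,0.66,0.53,0.18,0.00
L-OF-CT,L,OF,CT,0.46,0.00,0.59,0.00,0.00,0.43,0.54,0.41,0.71,0.09,1.00,0.00
L-ST-CT,L,ST,CT,0.53,0.08,0.65,0.00,0.00,0.39,0.47,0.35,0.61,0.02,1.00,0.00
L-IP-CT,L,IP,CT,0.37,0.00,0.51,0.00,0.00,0.34,0.63,0.49,0.79,0.08,1.00,0.00
L-DMF-CT,L,DMF,CT,0.42,0.00,0.68,0.16,0.00,0.53,0.42,0.32,0.55,0.06,0.51,0.00
L-AMT-CT,L,AMT,CT,0.52,0.07,0.65,0.03,0.00,0.43,0.45,0.35,0.58,0.02,0.88,0.00
L-PRC-CT,L,PRC,CT,0.09,0.00,0.51,0.31,0.00,0.50,0.60,0.47,0.74,0.74,0.22,0.00
L-DLP-CT,L,DLP,CT,0.28,0.00,0.57,0.17,0.00,0.51,0.55,0.43,0.70,0.31,0.56,0.00
L-PRS-CT,L,PRS,CT,0.34,0.00,0.59,0.12,0.00,0.48,0.54,0.41,0.69,0.16,0.60,0.00
R-C-CT,R,C,CT,0.44,0.00,0.57,0.00,0.00,0.40,0.56,0.43,0.72,0.07,1.00,0.00
R-O-CT,R,O,CT,0.41,0.00,0.60,0.07,0.00,0.47,0.52,0.40,0.68,0.10,0.78,0.00
R-PLT-CT,R,PLT,CT,0.14,0.00,0.49,0.19,0.00,0.43,0.67,0.51,0.84,0.61,0.44,0.00
R-SP-CT,R,SP,CT,0.33,0.00,0.61,0.17,0.00,0.55,0.50,0.39,0.63,0.20,0.54,0.00
R-OF-CT,R,OF,CT,0.55,0.30,0.67,0.00,0.00,0.18,0.45,0.33,0.61,0.00,1.00,0.00
R-ST-CT,R,ST,CT,0.20,0.00,0.58,0.25,0.00,0.51,0.55,0.41,0.71,0.40,0.23,0.00
R-IP-CT,R,IP,CT,0.00,0.00,0.42,0.32,0.00,0.45,0.68,0.55,0.82,1.00,0.16,0.00
R-DMF-CT,R,DMF,CT,0.44,0.09,0.56,0.00,0.00,0.29,0.56,0.44,0.72,0.02,1.00,0.00
R-AMT-CT,R,AMT,CT,0.20,0.00,0.55,0.21,0.00,0.48,0.59,0.45,0.75,0.42,0.35,0.00
R-PRC-CT,R,PRC,CT,0.38,0.00,0.52,0.00,0.00,0.34,0.62,0.48,0.78,0.06,1.00,0.00
R-DLP-CT,R,DLP,CT,0.53,0.27,0.65,0.00,0.00,0.20,0.47,0.35,0.62,0.00,1.00,0.00
R-PRS-CT,R,PRS,CT,0.17,0.00,0.56,0.26,0.00,0.51,0.56,0.43,0.72,0.48,0.25,0.00
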