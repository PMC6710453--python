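family,parameter,segment,mean,se,bf,bf_censored
within,HR,Q1,3.57,0.28,1000.0,True
within,HR,R1,-1.18,0.21,1000.0,True
within,HR,Q2,2.77,0.3,1000.0,True
within,HR,R2a,-0.93,0.24,106.23,False
within,HR,R2b,-0.33,0.3,0.26,False
within,HR,R2c,0.45,0.29,0.46,False
within,HR,R2d,0.3,0.26,0.28,False
within,HR,R2e,0.63,0.27,1.98,False
within,HR,R2f,0.89,0.27,24.15,False
within,MAP,R1,0.27,0.56,0.17,False
within,MAP,R2f,0.41,0.44,0.22,False
within,lnHF,Q1,-0.79,0.12,1000.0,True
within,lnHF,R1,0.08,0.07,0.31,False
within,lnHF,Q2,-0.88,0.14,1000.0,True
within,lnHF,R2a,0.13,0.08,0.54,False
within,lnHF,R2b,-0.2,0.07,5.07,False
within,lnHF,R2c,-0.16,0.07,2.31,False
within,lnHF,R2d,-0.21,0.07,11.65,False
within,lnHF,R2e,-0.22,0.08,3.1,False
within,lnHF,R2f,-0.25,0.08,19.31,False
within,lnLF,Q1,-0.2,0.13,0.45,False
within,lnLF,R1,0.18,0.08,1.52,False
within,lnLF,Q2,-0.26,0.13,1.04,False
within,lnLF,R2a,0.25,0.09,6.01,False
within,lnLF,R2b,-0.05,0.08,0.18,False
within,lnLF,R2c,-0.03,0.09,0.16,False
within,lnLF,R2d,-0.09,0.1,0.21,False
within,lnLF,R2e,-0.04,0.09,0.16,False
within,lnLF,R2f,0.09,0.09,0.23,False
within,RR,Q1,3.68,0.77,1000.0,True
within,RR,R1,0.78,0.58,0.34,False
within,RR,Q2,3.7,0.63,1000.0,True
within,RR,R2a,0.18,0.57,0.16,False
within,RR,R2b,1.07,0.65,0.52,False
within,RR,R2c,1.5,0.46,17.89,False
within,RR,R2d,1.34,0.51,3.58,False
within,RR,R2e,0.95,0.57,0.54,False
within,RR,R2f,0.01,0.54,0.15,False
within,NSFR,Q1,5.84,0.82,1000.0,True
within,NSFR,R1,0.39,0.58,0.18,False
within,NSFR,Q2,6.33,1.39,1000.0,True
within,NSFR,R2a,0.48,1.0,0.17,False
within,NSFR,R2b,-1.18,0.85,0.36,False
within,NSFR,R2c,-0.95,0.85,0.27,False
within,NSFR,R2d,-0.72,0.91,0.2,False
within,NSFR,R2e,-0.27,1.0,0.15,False
within,NSFR,R2f,-1.07,0.8,0.35,False
within,PEP,Q1,-3.1,2.27,0.36,False
within,PEP,R1,-0.68,2.26,0.15,False
within,PEP,Q2,-3.43,2.48,0.37,False
within,PEP,R2a,-0.71,1.78,0.16,False
within,PEP,R2b,1.54,1.86,0.2,False
within,PEP,R2c,0.01,2.62,0.15,False
within,PEP,R2d,1.39,2.1,0.18,False
within,PEP,R2e,1.36,2.18,0.18,False
within,PEP,R2f,0.02,1.74,0.15,False
within,CO,Q1,0.37,0.47,0.2,False
within,CO,R1,0.89,1.2,0.19,False
within,CO,Q2,0.69,0.57,0.3,False
within,CO,R2a,0.03,0.41,0.15,False
within,CO,R2b,-0.22,0.53,0.16,False
within,CO,R2c,-0.09,0.47,0.15,False
within,CO,R2d,-0.1,0.46,0.15,False
within,CO,R2e,-0.07,0.43,0.15,False
within,CO,R2f,0.13,0.51,0.15,False
within,TPR,Q1,-0.24,0.17,0.4,False
within,TPR,R1,0.35,0.17,1.12,False
within,TPR,Q2,-0.04,0.2,0.15,False
within,TPR,R2a,0.22,0.2,0.27,False
within,TPR,R2b,0.18,0.18,0.25,False
within,TPR,R2c,0.08,0.14,0.17,False
within,TPR,R2d,0.06,0.16,0.16,False
within,TPR,R2e,0.05,0.16,0.15,False
within,TPR,R2f,-0.11,0.17,0.18,False
between,HR,Q1,-0.06,0.53,0.15,False
between,HR,R1,0.01,0.43,0.15,False
between,HR,Q2,-0.24,0.57,0.16,False
between,HR,R2a,-0.18,0.54,0.16,False
between,HR,R2b,-0.25,0.56,0.16,False
between,HR,R2c,-0.46,0.54,0.21,False
between,HR,R2d,-0.39,0.53,0.19,False
between,HR,R2e,-0.53,0.57,0.22,False
between,HR,R2f,-0.39,0.51,0.2,False
between,MAP,R1,1.44,1.03,0.37,False
between,MAP,R2f,1.73,0.85,1.01,False
between,lnHF,Q1,0.24,0.25,0.23,False
between,lnHF,R1,-0.07,0.13,0.17,False
between,lnHF,Q2,0.05,0.25,0.15,False
between,lnHF,R2a,0.05,0.14,0.16,False
between,lnHF,R2b,-0.02,0.14,0.15,False
between,lnHF,R2c,0.15,0.14,0.26,False
between,lnHF,R2d,0.02,0.13,0.15,False
between,lnHF,R2e,0.09,0.16,0.17,False
between,lnHF,R2f,0.19,0.15,0.34,False
between,lnLF,Q1,-0.24,0.24,0.24,False
between,lnLF,R1,-0.13,0.16,0.21,False
between,lnLF,Q2,-0.29,0.22,0.33,False
between,lnLF,R2a,-0.21,0.17,0.3,False
between,lnLF,R2b,-0.1,0.17,0.17,False
between,lnLF,R2c,-0.02,0.17,0.15,False
between,lnLF,R2d,0.07,0.19,0.16,False
between,lnLF,R2e,0.09,0.18,0.17,False
between,lnLF,R2f,0.27,0.17,0.53,False
between,RR,Q1,-0.65,0.74,0.21,False
between,RR,R1,0.7,0.83,0.21,False
between,RR,Q2,-0.3,0.69,0.16,False
between,RR,R2a,0.05,1.06,0.15,False
between,RR,R2b,0.16,1.51,0.15,False
between,RR,R2c,0.08,0.75,0.15,False
between,RR,R2d,0.45,1.05,0.16,False
between,RR,R2e,-0.1,0.94,0.15,False
between,RR,R2f,0.36,0.94,0.16,False
between,NSFR,Q1,-0.15,2.11,0.15,False
between,NSFR,R1,-0.64,1.2,0.17,False
between,NSFR,Q2,-0.77,1.51,0.17,False
between,NSFR,R2a,-0.38,1.29,0.15,False
between,NSFR,R2b,0.11,1.18,0.15,False
between,NSFR,R2c,-0.81,1.29,0.18,False
between,NSFR,R2d,-0.54,1.57,0.16,False
between,NSFR,R2e,-0.82,1.66,0.17,False
between,NSFR,R2f,-1.47,1.49,0.23,False
between,PEP,Q1,-1.82,3.87,0.16,False
between,PEP,R1,0.6,3.8,0.15,False
between,PEP,Q2,-1.15,3.32,0.16,False
between,PEP,R2a,-1.37,3.45,0.16,False
between,PEP,R2b,-0.05,3.42,0.15,False
between,PEP,R2c,-2.6,4.74,0.17,False
between,PEP,R2d,-3.38,3.25,0.25,False
between,PEP,R2e,-3.12,3.9,0.2,False
between,PEP,R2f,-0.47,3.29,0.15,False
between,CO,Q1,0.91,0.86,0.25,False
between,CO,R1,2.08,2.27,0.22,False
between,CO,Q2,0.9,0.91,0.24,False
between,CO,R2a,1.16,0.98,0.29,False
between,CO,R2b,0.62,1.08,0.17,False
between,CO,R2c,1.17,0.9,0.33,False
between,CO,R2d,0.85,0.74,0.28,False
between,CO,R2e,0.72,0.78,0.22,False
between,CO,R2f,0.85,0.75,0.27,False
between,TPR,Q1,0.05,0.34,0.15,False
between,TPR,R1,0.04,0.34,0.15,False
between,TPR,Q2,0.24,0.41,0.17,False
between,TPR,R2a,0.12,0.4,0.15,False
between,TPR,R2b,0.71,0.35,0.96,False
between,TPR,R2c,0.01,0.3,0.15,False
between,TPR,R2d,-0.16,0.32,0.17,False
between,TPR,R2e,0.04,0.33,0.15,False
between,TPR,R2f,0.42,0.35,0.29,False
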