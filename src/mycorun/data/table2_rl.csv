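substrate,rl_mean_cm,significance_letters
S1,0.00,v
S2,6.80,r
S3,6.80,r
S4,6.80,r
S5,9.15,h-n
S6,10.10,bcd
S7,9.62,e-i
S8,9.02,lmn
S9,9.30,h-n
S10,9.60,e-j
S11,10.57,a
S12,9.57,e-k
S13,10.30,abc
S14,9.75,d-h
S15,9.90,def
S16,10.60,a
S17,5.20,u
S18,5.20,u
S19,9.00,lmn
S20,9.07,k-n
S21,9.47,f-m
S22,9.47,f-m
S23,9.72,d-h
S24,10.02,cde
S25,9.77,d-h
S26,10.45,ab
S27,9.37,g-m
S28,9.15,i-n
S29,9.67,e-i
S30,9.57,f-l
S31,9.50,f-l
S32,9.20,i-n
S33,5.05,u
S34,5.12,u
S35,5.12,u
S36,7.20,q
S37,9.60,f-j
S38,9.60,f-j
S39,9.72,d-h
S40,10.12,bcd
S41,9.12,j-n
S42,9.67,d-i
S43,9.30,h-n
S44,9.27,i-n
S45,9.82,d-g
S46,9.75,d-h
S47,10.57,a
S48,8.97,mn
S49,5.97,t
S50,6.05,st
S51,6.32,s
S52,5.87,t
S53,9.45,f-m
S54,10.35,abc
S55,8.82,no
S56,8.57,o
S57,7.62,p
S58,9.27,h-m
S59,9.25,h-m
S60,9.25,h-m
S61,9.35,g-m
S62,9.10,k-n
S63,9.62,e-i
S64,9.60,e-j
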