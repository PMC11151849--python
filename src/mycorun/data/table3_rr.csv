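substrate,rr_mean_cm_per_day,significance_letters
S1,0.000,z
S2,0.170,wx
S3,0.170,wx
S4,0.170,wx
S5,0.305,n-r
S6,0.337,f-i
S7,0.321,j-m
S8,0.301,pqr
S9,0.310,l-q
S10,0.320,j-o
S11,0.3525,de
S12,0.319,k-o
S13,0.343,efg
S14,0.325,h-l
S15,0.330,h-k
S16,0.353,de
S17,0.150,y
S18,0.148,y
S19,0.257,t
S20,0.302,pqr
S21,0.316,k-p
S22,0.316,k-p
S23,0.324,i-m
S24,0.334,g-j
S25,0.391,a
S26,0.348,ef
S27,0.312,l-q
S28,0.305,n-r
S29,0.387,a
S30,0.383,a
S31,0.380,ab
S32,0.368,c
S33,0.144,y
S34,0.146,y
S35,0.171,w
S36,0.240,u
S37,0.320,j-o
S38,0.320,j-o
S39,0.320,j-o
S40,0.338,fgh
S41,0.304,o-r
S42,0.387,a
S43,0.372,bc
S44,0.371,bc
S45,0.393,a
S46,0.390,a
S47,0.352,de
S48,0.299,qr
S49,0.149,y
S50,0.151,y
S51,0.158,xy
S52,0.147,y
S53,0.315,k-p
S54,0.345,efg
S55,0.294,rs
S56,0.286,s
S57,0.218,v
S58,0.309,l-q
S59,0.308,m-r
S60,0.308,m-r
S61,0.312,l-q
S62,0.364,cd
S63,0.385,a
S64,0.384,a
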