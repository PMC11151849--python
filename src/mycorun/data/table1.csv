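substrate,bagasse_pct,wheatbran_pct,beechsawdust_pct,days_to_highest
S1,0,0,0,
S2,0,0,25,40
S3,0,0,50,40
S4,0,0,100,40
S5,0,25,0,30
S6,0,25,25,30
S7,0,25,50,30
S8,0,25,100,30
S9,0,50,0,30
S10,0,50,25,30
S11,0,50,50,30
S12,0,50,100,30
S13,0,100,0,30
S14,0,100,25,30
S15,0,100,50,30
S16,0,100,100,30
S17,25,0,0,35
S18,25,0,25,35
S19,25,0,50,35
S20,25,0,100,30
S21,25,25,0,30
S22,25,25,25,30
S23,25,25,50,30
S24,25,25,100,30
S25,25,50,0,25
S26,25,50,25,30
S27,25,50,50,30
S28,25,50,100,30
S29,25,100,0,25
S30,25,100,25,25
S31,25,100,50,25
S32,25,100,100,25
S33,50,0,0,35
S34,50,0,25,35
S35,50,0,50,30
S36,50,0,100,30
S37,50,25,0,30
S38,50,25,25,30
S39,50,25,50,30
S40,50,25,100,30
S41,50,50,0,30
S42,50,50,25,25
S43,50,50,50,25
S44,50,50,100,25
S45,50,100,0,25
S46,50,100,25,25
S47,50,100,50,30
S48,50,100,100,30
S49,100,0,0,40
S50,100,0,25,40
S51,100,0,50,40
S52,100,0,100,40
S53,100,25,0,30
S54,100,25,25,30
S55,100,25,50,30
S56,100,25,100,30
S57,100,50,0,35
S58,100,50,25,30
S59,100,50,50,30
S60,100,50,100,30
S61,100,100,0,30
S62,100,100,25,25
S63,100,100,50,25
S64,100,100,100,25
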