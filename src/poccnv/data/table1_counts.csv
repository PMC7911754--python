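stratum,n,mean_age,normal,abnormal
1,540,30.47,262,278
2,586,31.63,208,378
3,283,32.43,122,161
4+,147,33.95,69,78
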