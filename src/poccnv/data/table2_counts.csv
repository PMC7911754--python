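stratum,autosomal_trisomy,autosomal_monosomy,mosaic_or_triploidy,partial_imbalance,monosomy_x,other
1,187,3,12,37,39,0
2,231,4,23,86,32,2
3,103,0,7,35,13,3
4+,51,1,4,15,7,0
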