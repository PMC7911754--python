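item,value
cases_with_cnvs,173
duplications,272
deletions,2
duplications_with_deletions,72
recurrent_cnvs_rpl,74
dup_16q24.3_carriers_rpl,19
dup_16q24.3_carriers_sa,0
dup_16q24.3_size_mb,1.65
dup_16p13.3_carriers_rpl,18
dup_16p13.3_carriers_sa,0
dup_16p13.3_size_mb,7.9
n_rpl,1016
n_sa,540
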