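# 24 variants removed when pruning heterogeneity contributions at the
# 98th percentile
rs10493326
rs4587594
rs2642438
rs903319
rs7422339
rs1250229
rs1515110
rs7640978
rs2240327
rs2602836
rs4976033
rs205262
rs12525163
rs17145738
rs799160
rs4921914
rs8176720
rs579459
rs653178
rs6489818
rs1186380
rs1169288
rs4465830
rs3761445
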