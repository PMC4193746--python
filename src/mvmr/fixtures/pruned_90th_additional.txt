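# 11 further variants removed when pruning at the 90th percentile
rs2290547
rs9686661
rs4917014
rs2326077
rs4871137
rs7832643
rs1781930
rs10832962
rs12801636
rs8017377
rs952044
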