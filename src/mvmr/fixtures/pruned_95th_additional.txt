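# 7 further variants removed when pruning at the 95th percentile
rs17345563
rs998584
rs3996352
rs2412710
rs9930333
rs8077889
rs4148005
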