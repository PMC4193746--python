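# 23 lipid-associated variants with known associations (P<0.05) with
# systolic/diastolic blood pressure or body mass index
rs4660293
rs2710642
rs2290547
rs3822072
rs13107325
rs6450176
rs1800562
rs998584
rs702485
rs2293889
rs1883025
rs2068888
rs12801636
rs653178
rs4983559
rs2652834
rs3198697
rs2000999
rs2925979
rs731839
rs492602
rs181362
rs5763662
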