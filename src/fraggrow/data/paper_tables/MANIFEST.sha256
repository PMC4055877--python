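9657dccc0dea1ec5b1fe0e30418bee34893185be6d2b018b9ed3d34a9ea12ab4  targets.csv
ea069384dbbf410363b898fd542678619e87d88519604778339dceeac6b10ecf  ensemble.csv
6f0024560c0335c846ed8021a8de780baf5bad9639cfdf8e2310ceea799c28a6  lead_spiking.csv
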