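compound_id,ki_htaar1_nM,ki_a2adr_nM,provenance
5a,1640,98.4,printed individually
6a,400,1880,printed individually
6c,36,162,printed individually
16,22,521,printed individually
17,32,128,derived by elimination from the 16/17 range pair
18,69,62,printed individually
19,110,330,derived by elimination from the 18/19 range pair
23,,288,alpha2-ADR value printed individually; hTAAR1 not printed
24,6,840,printed individually
37,12,74,printed individually
53,68,4352,printed individually
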