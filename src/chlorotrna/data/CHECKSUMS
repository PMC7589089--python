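d821ee7def433f84f1932fab4fe0181e4910ddd5f9457bf26e20eaaee3d0b64f  table1_nc64a.tsv
f80a4101ab1f5aaccc2c9059e811a584c77d76043b07621e1c49668c6b412dad  table2_sag.tsv
ba678eb3a5c659adf9e0494b2922f89385690e1a949c0e79dc5632aca787cc5a  table3_pbi.tsv
fabad729397af5e741836e9060de6b0dd9ec28d5f60fbb8941c6771874083c23  table4_presence.tsv
1654cec96108d7ee2d6025fdb941aa96d31dbf0249fcd3399f9b37ec2638eedc  table5_codon_usage.tsv
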