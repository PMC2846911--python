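#site_type branch
#intron_class U2_GCAG
#species synthetic
#exon_offset 0
2500 2500 2500 2500
2500 2500 2500 2500
2500 2500 2500 2500
1500 5500 1500 1500
1500 1500 1500 5500
2750 2250 2750 2250
5500 1500 1500 1500
1500 5500 1500 1500
1500 1500 1500 5500
2500 2500 2500 2500
2500 2500 2500 2500
2500 2500 2500 2500
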